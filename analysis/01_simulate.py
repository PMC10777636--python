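"""Generate the synthetic soil-community dataset used by the analysis.

Writes the OTU count table (400 taxa x 12 samples), taxonomy, sample
metadata (3 zones x 4 replicates), the soil-function table, and the
planted ground truth to results/data/.
"""

from pathlib import Path

from coremf.simulate import SyntheticConfig, write_dataset

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    config = SyntheticConfig(seed=SEED)
    paths = write_dataset(config, OUTDIR)
    print(f"simulated {config.n_taxa} taxa x {config.n_samples} samples "
          f"({config.depth} reads/sample), {config.n_core} planted core taxa, "
          f"{config.n_modules} modules")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
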