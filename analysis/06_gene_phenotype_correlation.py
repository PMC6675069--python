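"""Rank DSS-altered genes by correlation with average rear duration.

Correlates each significant gene's normalized expression with the
per-animal average rear duration across all 10 animals and prints the top
genes on each sign, linking transcriptional state to the behavioral pain
surrogate.
"""

from pathlib import Path

import pandas as pd

from colitis_metasig.pipeline import RunConfig, run_pipeline

SEED = 7
OUT = "results/pipeline"


def main() -> None:
    cfg = RunConfig(seed=SEED, out_dir=OUT)  # all stages
    run_pipeline(cfg)
    for sign in ("negative", "positive"):
        top = pd.read_csv(
            Path(OUT) / f"correlation_top_{sign}.tsv", sep="\t", index_col=0
        )
        head = top.head(5)
        print(f"top {sign}ly correlated genes (of {len(top)}):")
        for g, row in head.iterrows():
            print(f"  {g}  r = {row['r']:+.3f}  p = {row['p']:.3g}")


if __name__ == "__main__":
    main()
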