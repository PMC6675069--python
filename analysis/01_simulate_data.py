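"""Simulate the study's inputs with known ground truth.

Generates the control/DSS count matrix (100 planted perturbed genes at
|log2FC| = 1.5 among 1000), the 18-study human bioset panel whose planted
signature sits on human orthologs of the planted mouse genes, the partial
ortholog map (~81% of mouse genes mapped), and one 60-minute open-field
beam-break session per animal (DSS animals rear less, for shorter bouts).
Outputs and JSON ground-truth sidecars land under results/pipeline/.
"""

from colitis_metasig.pipeline import RunConfig, run_pipeline

SEED = 7
OUT = "results/pipeline"


def main() -> None:
    cfg = RunConfig(seed=SEED, out_dir=OUT, stages=["simulate"])
    report = run_pipeline(cfg)
    c = report["counts"]
    print(f"simulated {c['n_genes']} genes ({c['n_planted_de']} planted DE), "
          f"{c['n_planted_signature']}-gene planted bioset signature, "
          f"10 open-field sessions -> {OUT}")


if __name__ == "__main__":
    main()
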