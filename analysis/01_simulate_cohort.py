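"""Generate the synthetic two-condition resting-state cohort.

Emulated study conditions: 15 control-like and 15 patient-like (DOC-like)
subjects, one scan each of 215 volumes at TR = 2 s over a 20-region
bilateral atlas (a scaled-down stand-in for the 90-area parcellation that
keeps the downstream permutation statistics desk-tractable).  Controls get
strong homotopic coupling (0.8) and denser lagged directed edges; the
patient-like arm gets weak homotopic coupling (0.3 x severity) and sparser
edges, plus CRS-R scores tied to severity.

Writes scans/manifest/atlas/ground-truth under scratch/cohort/ and a small
design summary under results/.
"""

from pathlib import Path

import pandas as pd

from docfc.pipeline import PipelineConfig, simulate

ROOT = Path(__file__).resolve().parent.parent
CONFIG = PipelineConfig(
    data_dir=str(ROOT / "scratch" / "cohort"),
    out_dir=str(ROOT / "scratch" / "pipeline_out"),
    n_permutations=29,
    seed=1,
    cohort={"n_rois": 20, "n_subjects_per_group": 15},
)


def main() -> None:
    out = simulate(CONFIG)
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    doc = manifest[manifest.condition == "doc"]
    print(f"cohort written to {out}")
    print(f"  {len(manifest)} scans: {dict(manifest.condition.value_counts())}")
    print(f"  DOC severity range: {doc.severity.min():.2f}-{doc.severity.max():.2f}")
    print(f"  DOC CRS-R totals:   {doc.crsr_total.min():.0f}-{doc.crsr_total.max():.0f}"
          f" (scale maximum 23)")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    design = manifest.groupby("condition").agg(
        n=("subject_id", "count"),
        severity_mean=("severity", "mean"),
        crsr_total_mean=("crsr_total", "mean"))
    design.to_csv(results / "cohort_design.tsv", sep="\t", float_format="%.4g")
    print(f"  design summary -> {results / 'cohort_design.tsv'}")


if __name__ == "__main__":
    main()
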