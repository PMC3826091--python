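"""Distance-stratified homotopic connectivity and clinical-score correlations.

Two follow-up analyses on the per-scan connectivity results:

1. homologue-pair PC values binned by inter-centroid distance (<20 mm,
   20-40 mm, >40 mm) and compared between groups per bin — the synthetic
   homotopic coupling is distance-independent, so group separation is
   expected in every populated bin;
2. Pearson correlation of per-patient connectivity readouts (HIH PC,
   homologue/LL/RR TE category means) with the CRS-R subscales, total
   score, and months since injury.
"""

from pathlib import Path

import pandas as pd

from docfc.atlas import load_atlas
from docfc.cohort import read_cohort
from docfc.connectivity import ConnectivityResult
from docfc.groupstats import (crsr_correlation, distance_stratified_compare,
                              homologue_pair_values)

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
CONN_DIR = ROOT / "scratch" / "connectivity"
RESULTS = ROOT / "results"
GROUPS = ("control", "doc")


def main() -> None:
    atlas = load_atlas(COHORT_DIR / "atlas.tsv")
    scans, manifest = read_cohort(COHORT_DIR)
    pc_results = [ConnectivityResult.load(CONN_DIR, f"{s.subject_id}_pc")
                  for s in scans]
    pairs = pd.concat([homologue_pair_values(r, atlas) for r in pc_results],
                      ignore_index=True)
    by_bin = distance_stratified_compare(pairs, GROUPS)
    by_bin.to_csv(RESULTS / "distance_stratified_hih_pc.tsv", sep="\t",
                  index=False, float_format="%.6g")
    print("== HIH PC by homologue centroid distance (control vs doc) ==")
    print(by_bin.round(4).to_string(index=False), "\n")

    te_summary = pd.read_csv(RESULTS / "category_summaries_te.tsv", sep="\t")
    pc_summary = pd.read_csv(RESULTS / "category_summaries_pc.tsv", sep="\t")
    te_by = te_summary.pivot_table(index="subject_id", columns="category",
                                   values="mean_value", observed=False)
    measures = pd.DataFrame({
        "hih_pc": pc_summary[pc_summary.category == "HIH"]
        .set_index("subject_id")["mean_value"],
        "homologue_te": (te_by["HLR"] + te_by["HRL"]) / 2.0,
        "ll_te": te_by["LL"],
        "rr_te": te_by["RR"],
    }).reset_index()
    corr = crsr_correlation(measures, manifest)
    corr.to_csv(RESULTS / "crsr_correlations.tsv", sep="\t",
                index=False, float_format="%.4g")
    totals = corr[corr.score == "crsr_total"]
    print("== correlation with total CRS-R over patient scans ==")
    print(totals[["measure", "r", "p", "n"]].round(3).to_string(index=False))
    print(f"-> {RESULTS}/distance_stratified_hih_pc.tsv, "
          f"{RESULTS}/crsr_correlations.tsv")


if __name__ == "__main__":
    main()
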