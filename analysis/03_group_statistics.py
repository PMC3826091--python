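"""Compare connectivity between the control-like and patient-like groups.

Runs, per measure (PC, TE), the two-way ANOVA (group x category, Type II),
Bonferroni-corrected per-category post-hoc t-tests, and Kruskal-Wallis
tests on the per-scan category means produced by 02_connectivity.py.

The expected pattern, by construction of the generator: homologue
inter-hemispheric (HIH) PC sharply higher in controls; thresholded
intra-/inter-hemispheric TE higher in controls.
"""

import json
from pathlib import Path

import pandas as pd

from docfc.groupstats import (format_group_table, kruskal_wallis_by_category,
                              posthoc_bonferroni, two_way_anova)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
GROUPS = ("control", "doc")


def main() -> None:
    bundle = {}
    tables = []
    for measure in ("pc", "te"):
        summaries = pd.read_csv(RESULTS / f"category_summaries_{measure}.tsv", sep="\t")
        anova = two_way_anova(summaries, GROUPS)
        posthoc = posthoc_bonferroni(summaries, GROUPS)
        kruskal = kruskal_wallis_by_category(summaries, GROUPS)
        bundle[measure.upper()] = {
            "anova": anova.to_dict(orient="records"),
            "posthoc_bonferroni": posthoc.to_dict(orient="records"),
            "kruskal_wallis": kruskal.to_dict(orient="records"),
        }
        tables.append(f"== {measure.upper()}: mean +/- SD per group x category ==\n"
                      + format_group_table(summaries, GROUPS, posthoc))
        inter = anova.set_index("effect")
        print(f"{measure.upper()}: group x category interaction "
              f"F = {inter.loc['group:category', 'F']:.2f}, "
              f"p = {inter.loc['group:category', 'p']:.2g}")
        sig = posthoc[posthoc.p_bonferroni <= 0.05]
        print(f"  post-hoc significant categories (Bonferroni p <= 0.05): "
              f"{', '.join(sig.category) or 'none'}")
    (RESULTS / "group_stats.json").write_text(json.dumps(bundle, indent=2))
    (RESULTS / "group_tables.txt").write_text("\n\n".join(tables) + "\n")
    print(f"-> {RESULTS}/group_stats.json, {RESULTS}/group_tables.txt")


if __name__ == "__main__":
    main()
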