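#!/usr/bin/env python
"""Differential abundance: FTLD combined vs controls.

Per metabolite, an age- and sex-adjusted linear model on the z-scored
values, Benjamini-Hochberg correction at q = 0.01, a Bonferroni flag,
and fold changes on the unscaled imputed data.  Prints the counts and
the top hits; writes the full table.
"""

from pathlib import Path

from ftldmet import read_cohort, preprocess, run_univariate, write_results

BASE = Path(__file__).resolve().parent.parent / "results" / "study"

if __name__ == "__main__":
    sim = BASE / "simulate"
    matrix, pmap, meta = read_cohort(
        sim / "abundance.csv", sim / "pathways.csv", sim / "metadata.csv"
    )
    pre = preprocess(matrix, pmap)
    res = run_univariate(pre, meta)
    sig = res.significant
    print(f"{len(sig)} of {len(res.table)} metabolites significant at FDR q < 0.01")
    print(f"{int(res.table['bonferroni_flag'].sum())} survive Bonferroni correction")
    print("top 10 by raw p:")
    cols = ["metabolite", "subpathway", "fold_change", "p_fdr", "p_raw"]
    print(res.table[cols].head(10).to_string(index=False))
    write_results({"univariate": res.table}, BASE / "univariate")
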