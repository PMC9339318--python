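"""Lineage-specific subscale LRT and the length-stratified comparison.

Simulates three element classes with different lengths and foreground
acceleration (genes 900 bp, avian CNEEs 300 bp, owl CNEEs 250 bp; the
accelerated half evolves twice as fast on the diurnal tips), runs the
one-scale vs two-scale LRT, applies BH within class, and tabulates
log10(subscale) by class and length interval with the study's length
exclusions.
"""

from pathlib import Path

import pandas as pd

from owlaccel.rateshift import (add_subscale_fdr, fit_subscale_lrt,
                                summarize_subscale_by_length)
from owlaccel.simulate import (RegimeSpec, default_neutral_model,
                               fixture_tree, simulate_alignment)

OUT = Path(__file__).resolve().parent.parent / "results"

CLASSES = {"gene": 900, "avian_cnee": 300, "owl_cnee": 250}


def main(seed: int = 51, per_class: int = 20) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = fixture_tree()
    model = default_neutral_model(tree)
    results = []
    s = seed
    for cls, length in CLASSES.items():
        for i in range(per_class):
            accelerated = i < per_class // 2
            mult = {int(b): 1.0 for b in tree.branches}
            if accelerated:
                for b in tree.foreground:
                    mult[int(b)] = 2.0
            aln = simulate_alignment(tree, model,
                                     RegimeSpec("x", mult, length, 1),
                                     seed=s)[0]
            s += 1
            results.append(fit_subscale_lrt(aln, model, element_class=cls))
    add_subscale_fdr(results)
    df = pd.DataFrame([{
        "element": r.element, "class": r.element_class, "length": r.length,
        "subscale": r.subscale, "p": r.p, "q": r.q,
        "significant": r.significant} for r in results])
    df.to_csv(OUT / "subscale.tsv", sep="\t", index=False,
              float_format="%.6g")
    table = summarize_subscale_by_length(results)
    table.to_csv(OUT / "subscale_by_length.tsv", sep="\t", index=False,
                 float_format="%.6g")
    sig = df[df["significant"]]
    print(f"{len(sig)}/{len(df)} elements genome-wide significant "
          f"(subscale > 1 and q < 0.05)")
    print(f"median subscale among significant: {sig['subscale'].median():.2f}"
          f" (truth 2.0 for accelerated elements)")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
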