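#!/usr/bin/env python
"""Rate and proportion statistics on the published count tables.

Sectoring rates with Wilson 95% intervals, treatment fold changes,
chi-square and Fisher comparisons of event classes and timings, and the
SpeI genotype rule — everything recomputed from the raw counts.
"""

import json
from pathlib import Path

from sectorloh.stats import (
    chi_square_2x2,
    classify_spei_genotype,
    fisher_exact,
    fold_change,
    sectoring_rate,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results = {}

    top1d = sectoring_rate(35, 1_300_000)
    results["top1d_rate"] = {"rate": top1d.rate, "ci95": top1d.ci95}
    print(f"top1d sectoring rate: {top1d.rate:.2g}/division "
          f"(95% CI {top1d.ci95[0]:.2g}-{top1d.ci95[1]:.2g})")

    cpt, dmso = sectoring_rate(79, 310_000), sectoring_rate(4, 130_000)
    fc = fold_change(cpt, dmso)
    stat, p = chi_square_2x2([[79, 310_000 - 79], [4, 130_000 - 4]])
    results["cpt_chrIV"] = {"fold_change": fc, "chi2_p": p}
    print(f"CPT vs DMSO (chr IV): {fc:.1f}-fold, chi2 p = {p:.2g}")

    fc5 = fold_change(sectoring_rate(761, 50_000_000), sectoring_rate(190, 73_000_000))
    results["cpt_chrV_fold_change"] = fc5
    print(f"CPT vs control (chr V): {fc5:.1f}-fold")

    p_complex = fisher_exact([[41, 37], [39, 82]])
    results["complex_tract_fisher_p"] = p_complex
    print(f"complex tracts 41/78 vs 39/121: Fisher p = {p_complex:.3f}")

    p_simple = fisher_exact([[14, 23], [53, 29]])
    p_all = fisher_exact([[49, 29], [90, 31]])
    results["g1_g2_fisher"] = {"simple_conversions": p_simple, "all": p_all}
    print(f"G1/G2 simple conversions 14:23 vs 53:29: Fisher p = {p_simple:.4f}")
    print(f"G1/G2 all conversions 49:29 vs 90:31: Fisher p = {p_all:.2f}")

    p_hs7 = fisher_exact([[7, 132], [0, 88]])
    results["hs7_fisher_p"] = p_hs7
    print(f"HS7 inclusion 7/139 vs 0/88: Fisher p = {p_hs7:.3f}")

    for sizes in ((750, 500, 250), (500, 250), (750,)):
        call = classify_spei_genotype(sizes).call
        results.setdefault("spei_calls", {})[",".join(map(str, sizes))] = call
        print(f"SpeI fragments {sizes} -> {call}")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "rates_and_tests.json").write_text(json.dumps(results, indent=1))


if __name__ == "__main__":
    main()
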