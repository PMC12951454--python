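#!/usr/bin/env python
"""Sequence charge composition and design-set enrichment statistics.

Profiles the ubiquitin sequence (the 11 positive / 11 negative, net-zero
reference), shows the counterion rule on a 12/15 composition (net -3,
three cations), and measures charged-residue enrichment across a
500-variant synthetic design set built over the ubiquitin template.
"""

from pathlib import Path

import pandas as pd

from hydrashell import (
    UBIQUITIN_SEQUENCE,
    charge_profile,
    counterions_for_neutrality,
    enrichment_stats,
    make_design_set,
    substitution_map,
    write_fasta,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "seqcharge"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ub = charge_profile(UBIQUITIN_SEQUENCE, "KR_DE", "Ub")
    print(f"ubiquitin: {ub.n_positive} positive / {ub.n_negative} negative, "
          f"net {ub.net_charge:+d} e -> counterions {counterions_for_neutrality(ub)}")

    acidic = charge_profile("K" * 6 + "R" * 6 + "D" * 8 + "E" * 7 + "G" * 51, sequence_id="12/15")
    cations, anions = counterions_for_neutrality(acidic)
    print(f"12/15 composition: net {acidic.net_charge:+d} e -> "
          f"{cations} cations, {anions} anions")

    designs = make_design_set(UBIQUITIN_SEQUENCE, 500, extra_pos=4, extra_neg=5, seed=SEED)
    write_fasta(OUT / "designs.fasta", [("template", designs.template)] + designs.variants)
    stats = enrichment_stats(designs)
    rows = []
    for vid, seq in designs.variants[:10]:
        p = charge_profile(seq, sequence_id=vid)
        _, n_subs = substitution_map(designs.template, seq)
        rows.append((vid, p.n_positive, p.n_negative, p.net_charge, n_subs))
    pd.DataFrame(rows, columns=["variant", "n_positive", "n_negative",
                                "net_charge", "n_substitutions"]).to_csv(
        OUT / "variant_profiles_head.csv", index=False)
    pd.DataFrame({
        "delta_pct_positive": stats.deltas_pct_positive,
        "delta_pct_negative": stats.deltas_pct_negative,
    }).to_csv(OUT / "enrichment_deltas.csv", index=False)
    print(f"500 variants: mean enrichment {stats.mean_delta_pct_positive:.2f}% positive, "
          f"{stats.mean_delta_pct_negative:.2f}% negative "
          f"(sd {stats.sd_delta_pct_positive:.3f} / {stats.sd_delta_pct_negative:.3f})")


if __name__ == "__main__":
    main()
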