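"""Sequence charge composition, counterions and design-set enrichment.

Side-chain bookkeeping only: K and R count as positive, D and E as
negative (histidine optionally positive under the ``KRH_DE`` scheme),
termini excluded, no pKa model.  Under the default scheme wild-type
ubiquitin comes out at 11 positive / 11 negative, net 0, and a sequence
with net formal charge -3 needs exactly three monovalent cations for a
neutral simulation box.

Design-set statistics compare each variant's charged-residue percentages
against its template, the per-variant deltas summarised by mean and
standard deviation — the quantity that captures systematic surface-charge
enrichment across an inverse-folding design campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UBIQUITIN_SEQUENCE",
    "ChargeProfile",
    "EnrichmentSummary",
    "DesignSet",
    "charge_profile",
    "counterions_for_neutrality",
    "substitution_map",
    "enrichment_stats",
]

#: Canonical 76-residue ubiquitin sequence (human UBB repeat unit).
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ChargeProfile:
    sequence_id: str
    length: int
    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float
    net_charge: int


@dataclass(frozen=True)
class EnrichmentSummary:
    n_variants: int
    mean_delta_pct_positive: float
    mean_delta_pct_negative: float
    sd_delta_pct_positive: float
    sd_delta_pct_negative: float
    deltas_pct_positive: tuple
    deltas_pct_negative: tuple


@dataclass
class DesignSet:
    """A template plus variant sequences, with generator ground truth."""

    template: str
    variants: list[tuple[str, str]]  # (id, sequence)
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = sorted(set(seq) - _VALID)
    if bad:
        raise ValueError(f"illegal sequence characters: {bad}")
    return seq


def charge_profile(
    sequence: str,
    scheme: str = "KR_DE",
    sequence_id: str = "",
) -> ChargeProfile:
    """Count charged side-chains; termini excluded, full length as denominator."""
    seq = _check_sequence(sequence)
    if scheme == "KR_DE":
        positive = set("KR")
    elif scheme == "KRH_DE":
        positive = set("KRH")
    else:
        raise ValueError(f"unknown charge scheme {scheme!r}")
    n_pos = sum(c in positive for c in seq)
    n_neg = sum(c in "DE" for c in seq)
    n = len(seq)
    return ChargeProfile(
        sequence_id=sequence_id,
        length=n,
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=n_pos / n * 100.0 if n else 0.0,
        pct_negative=n_neg / n * 100.0 if n else 0.0,
        net_charge=n_pos - n_neg,
    )


def counterions_for_neutrality(profile: ChargeProfile) -> tuple[int, int]:
    """(n_cations, n_anions) of monovalent ions restoring net charge zero."""
    net = profile.net_charge
    return (max(0, -net), max(0, net))


def substitution_map(
    template: str,
    variant: str,
    offset: int = 0,
) -> tuple[list[tuple[int, str, str]], int]:
    """Positions (1-based, template numbering) where the variant differs.

    ``offset`` shifts the variant relative to the template before the
    position-wise comparison; the overlapping stretch must match in length.
    """
    tpl = _check_sequence(template)
    var = _check_sequence(variant)
    if offset:
        var = var[offset:] if offset > 0 else ("X" * (-offset) + var)
    if len(tpl) != len(var):
        raise ValueError(
            f"length mismatch: template {len(tpl)} vs variant {len(var)} (offset {offset})"
        )
    subs = [(i + 1, a, b) for i, (a, b) in enumerate(zip(tpl, var)) if a != b]
    return subs, len(subs)


def enrichment_stats(
    designs: DesignSet,
    template: str | None = None,
    scheme: str = "KR_DE",
) -> EnrichmentSummary:
    """Charged-residue enrichment of a design set over its template.

    Per variant: delta in percent positive and percent negative relative
    to the template profile; summarised by mean and population standard
    deviation across the set.
    """
    if designs.n_variants == 0:
        raise ValueError("design set is empty")
    tpl = template if template is not None else designs.template
    ref = charge_profile(tpl, scheme)
    d_pos, d_neg = [], []
    for _vid, seq in designs.variants:
        p = charge_profile(seq, scheme)
        d_pos.append(p.pct_positive - ref.pct_positive)
        d_neg.append(p.pct_negative - ref.pct_negative)
    d_pos = np.array(d_pos)
    d_neg = np.array(d_neg)
    return EnrichmentSummary(
        n_variants=designs.n_variants,
        mean_delta_pct_positive=float(d_pos.mean()),
        mean_delta_pct_negative=float(d_neg.mean()),
        sd_delta_pct_positive=float(d_pos.std()),
        sd_delta_pct_negative=float(d_neg.std()),
        deltas_pct_positive=tuple(float(x) for x in d_pos),
        deltas_pct_negative=tuple(float(x) for x in d_neg),
    )
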