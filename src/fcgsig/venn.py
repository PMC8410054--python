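"""Decomposition of the four genotype responses into shared regions.

Region E holds genes responding in all four genotypes; regions A-D hold the
gonadal-female (XXF&XYF), gonadal-male (XXM&XYM), chromosomal-female
(XXF&XXM) and chromosomal-male (XYF&XYM) shared responses after removing E.
Sharing is direction-concordant by default: a gene counts as shared only if
it moves the same way in every signature of the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .de import Signature

REGION_AXES = {
    "A": ("XXF", "XYF"),   # gonadal female
    "B": ("XXM", "XYM"),   # gonadal male
    "C": ("XXF", "XXM"),   # chromosomal female
    "D": ("XYF", "XYM"),   # chromosomal male
}


@dataclass
class VennDecomposition:
    """Directional region membership (gene -> 'up'/'down') per region."""

    regions: dict[str, dict[str, str]]
    discordant: dict[str, set] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        rows = []
        for region in ("A", "B", "C", "D", "E"):
            members = self.regions.get(region, {})
            n_up = sum(1 for d in members.values() if d == "up")
            n_down = len(members) - n_up
            rows.append({"region": region, "up": n_up, "down": n_down,
                         "total": len(members)})
        return pd.DataFrame(rows).set_index("region")

    def to_summary(self) -> dict:
        counts = self.counts()
        return {
            "counts": {r: {"up": int(row["up"]), "down": int(row["down"])}
                       for r, row in counts.iterrows()},
            "discordant": {k: sorted(v) for k, v in self.discordant.items()},
        }


def _shared(maps: list[Mapping[str, str]],
            concordant: bool) -> tuple[dict[str, str], set]:
    """Genes present in every map; returns (concordant members, discordant)."""
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    members: dict[str, str] = {}
    discordant: set = set()
    for gene in common:
        directions = {m[gene] for m in maps}
        if len(directions) == 1:
            members[gene] = next(iter(directions))
        elif concordant:
            discordant.add(gene)
        else:
            members[gene] = maps[0][gene]
    return members, discordant


def decompose(
    sig_xxf: Signature,
    sig_xxm: Signature,
    sig_xyf: Signature,
    sig_xym: Signature,
    require_concordance: bool = True,
) -> VennDecomposition:
    """Partition four genotype signatures into regions A-E.

    E (shared by all four) is computed first; each axis region then holds the
    genes shared by its two genotypes minus anything present in all four.
    Genes present in all four with conflicting directions are excluded from
    every region and tracked in ``discordant``.
    """
    sigs = {"XXF": sig_xxf, "XXM": sig_xxm, "XYF": sig_xyf, "XYM": sig_xym}
    ids = [id(s) for s in sigs.values()]
    if len(set(ids)) != len(ids):
        raise ValueError("the same Signature object was passed for more "
                         "than one genotype")

    maps = {g: s.directions() for g, s in sigs.items()}
    region_e, disc_e = _shared(list(maps.values()), require_concordance)
    all_four = set(region_e) | disc_e

    regions: dict[str, dict[str, str]] = {"E": region_e}
    discordant: dict[str, set] = {"E": disc_e}
    for region, (ga, gb) in REGION_AXES.items():
        shared, disc = _shared([maps[ga], maps[gb]], require_concordance)
        regions[region] = {g: d for g, d in shared.items()
                           if g not in all_four}
        discordant[region] = disc - all_four
    return VennDecomposition(regions=regions, discordant=discordant)


def _directional_pairs(sig: Signature) -> set:
    return {(g, "up") for g in sig.up} | {(g, "down") for g in sig.down}


def overlap_percentage(sig_a: Signature, sig_b: Signature,
                       denominator: str = "union") -> float:
    """Percent directional overlap between two signatures.

    ``denominator='union'`` gives 100 x Jaccard; ``'smaller'`` divides by the
    smaller signature instead. Returns 0 when both are empty.
    """
    a, b = _directional_pairs(sig_a), _directional_pairs(sig_b)
    inter = len(a & b)
    if denominator == "union":
        denom = len(a | b)
    elif denominator == "smaller":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * inter / denom if denom else 0.0


def direction_fraction(region: Mapping[str, str]) -> tuple[float, float]:
    """(percent up, percent down) of a directional region; (0,0) if empty."""
    if not region:
        return (0.0, 0.0)
    n_up = sum(1 for d in region.values() if d == "up")
    pct_up = 100.0 * n_up / len(region)
    return (pct_up, 100.0 - pct_up)
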