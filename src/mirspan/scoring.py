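"""Pair-level scoring: weighted energy totals and the dual-cutoff call.

Each miRNA-gene pair is summarised over all of its seed sites:

    Total_dG_duplex = sum_sites W(type, region) * dG_duplex(site)
    Total_ddG       = sum_sites W(type, region) * ddG(site)

where W is the SNR-derived weight of the site's (seed type, gene region)
cell.  Every site occurrence contributes its own term — sites sharing a
(type, region) cell are not collapsed.  A pair is called a putative target
when BOTH totals are strictly below their cutoffs (default preset
-15.0 / -10.0 kcal/mol; stringent preset -25.0 / -14.0 kcal/mol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .background import WeightTable, WeightingError
from .energetics import EnergyParams, SiteEnergies, extract_window, site_energies
from .seedscan import SeedSite, scan_sites
from .seqmodel import GeneRegions, MiRNA, REGION_ORDER

__all__ = [
    "Cutoffs",
    "PairScore",
    "SiteContribution",
    "score_pair",
    "call_target",
    "rank_predictions",
    "predict_pair",
    "predict_targets",
    "PRESETS",
]


@dataclass(frozen=True)
class Cutoffs:
    """Dual energy cutoffs (kcal/mol); both must be beaten for a call."""

    dG_duplex_cutoff: float
    ddG_cutoff: float

    def __post_init__(self) -> None:
        for name in ("dG_duplex_cutoff", "ddG_cutoff"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")
            if v > 0:
                warnings.warn(
                    f"{name} = {v} is positive; cutoffs are normally "
                    "negative energies",
                    stacklevel=2,
                )


#: cutoff presets: 'default' trades coverage against accuracy, 'stringent'
#: matches the accuracy of conservation-filtered predictors
PRESETS: Mapping[str, Cutoffs] = {
    "default": Cutoffs(-15.0, -10.0),
    "stringent": Cutoffs(-25.0, -14.0),
}


@dataclass(frozen=True)
class SiteContribution:
    site: SeedSite
    weight: float
    energies: SiteEnergies


@dataclass
class PairScore:
    """Weighted energy summary of one miRNA-gene pair."""

    mirna_id: str
    gene_id: str
    total_dG_duplex: float
    total_ddG: float
    breakdown: list[SiteContribution] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.breakdown)


def score_pair(
    mirna_id: str,
    gene_id: str,
    sites_with_energies: Sequence[tuple[SeedSite, SiteEnergies]],
    weights: WeightTable,
) -> PairScore:
    """Weighted sums over a pair's sites.

    Sites whose weight cell was clamped to 0 remain in the breakdown with
    zero contribution (site counts stay informative).  A site whose
    (type, region) cell is undefined raises WeightingError naming the cell.
    """
    total_dg = 0.0
    total_ddg = 0.0
    breakdown: list[SiteContribution] = []
    for site, energies in sites_with_energies:
        w = weights.weight(site.seed_type, site.region)  # raises on NaN cell
        total_dg += w * energies.dG_duplex
        total_ddg += w * energies.ddG
        breakdown.append(SiteContribution(site=site, weight=w, energies=energies))
    return PairScore(
        mirna_id=mirna_id,
        gene_id=gene_id,
        total_dG_duplex=total_dg,
        total_ddG=total_ddg,
        breakdown=breakdown,
    )


def call_target(score: PairScore, cutoffs: Cutoffs) -> bool:
    """Putative-target call: both totals strictly below their cutoffs."""
    return (
        score.total_dG_duplex < cutoffs.dG_duplex_cutoff
        and score.total_ddG < cutoffs.ddG_cutoff
    )


def rank_predictions(scores: Iterable[PairScore]) -> list[PairScore]:
    """Stable deterministic ordering: ascending Total_ddG, then ascending
    Total_dG_duplex, then gene id, then miRNA id."""
    return sorted(
        scores,
        key=lambda s: (s.total_ddG, s.total_dG_duplex, s.gene_id, s.mirna_id),
    )


def predict_pair(
    mirna: MiRNA,
    gene: GeneRegions,
    weights: WeightTable,
    params: EnergyParams,
) -> PairScore:
    """Scan one miRNA against one gene, compute per-site energies on the
    context windows, and summarise.

    ``params`` is either an :class:`EnergyParams` set for the bundled
    engine, or any object exposing ``site_energies(mirna_seq, window)``
    (e.g. the external-library adapter).
    """
    entries: list[tuple[SeedSite, SiteEnergies]] = []
    # energies depend only on the window content: cache per window
    cache: dict[tuple[str, int, int], SiteEnergies] = {}
    for site in scan_sites(mirna, gene):
        window = extract_window(gene[site.region], site)
        key = (window.sequence, window.site_start, window.site_end)
        energies = cache.get(key)
        if energies is None:
            if hasattr(params, "site_energies"):
                energies = params.site_energies(mirna.sequence, window)
            else:
                energies = site_energies(mirna.sequence, window, params)
            cache[key] = energies
        entries.append((site, energies))
    return score_pair(mirna.id, gene.gene_id, entries, weights)


def predict_targets(
    mirnas: Sequence[MiRNA],
    genes: Mapping[str, GeneRegions],
    weights: WeightTable,
    params: EnergyParams,
    cutoffs: Cutoffs,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[tuple[PairScore, bool]]:
    """Score miRNA-gene pairs and call targets.

    ``pairs`` restricts scoring to the given (mirna_id, gene_id) list;
    by default every miRNA is scored against every gene.  Results are
    returned in rank order with their calls.
    """
    by_id = {m.id: m for m in mirnas}
    if pairs is None:
        todo = [(m.id, g) for m in mirnas for g in genes]
    else:
        todo = list(pairs)
    scores = []
    for mirna_id, gene_id in todo:
        if mirna_id not in by_id:
            raise KeyError(f"unknown miRNA id {mirna_id!r}")
        if gene_id not in genes:
            raise KeyError(f"unknown gene id {gene_id!r}")
        scores.append(predict_pair(by_id[mirna_id], genes[gene_id], weights, params))
    return [(s, call_target(s, cutoffs)) for s in rank_predictions(scores)]
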