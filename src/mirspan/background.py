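"""Shuffle-calibrated enrichment: signal-to-noise ratios and site weights.

Seed matches of a given type and gene region are informative to the extent
that verified miRNA-gene pairs contain more of them than expected by
chance.  The background model is a mononucleotide shuffle of each region
sequence: observed site counts in a verified corpus are divided by the
mean count over shuffled replicates, giving a per-(type, region)
signal-to-noise ratio (SNR).  SNRs are converted to site weights relative
to a reference cell (the strongest one, canonically 8-mer-with-A1 matches
in 3'UTRs, which gets weight 1):

    W_ij = (SNR_ij - 1) / (SNR_ref - 1)

Cells with SNR below 1 (depleted site classes) are clamped to weight 0 so
they cannot shrink a score's magnitude.

Counting is per site occurrence, not per gene: a pair with three 2t8 sites
in its CDS contributes 3 to that cell.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seedscan import SEED_TYPE_ORDER, SeedType, count_sites_by_type, encode
from .seqmodel import GeneRegions, MiRNA, REGION_ORDER, RegionKind

__all__ = [
    "CountMatrix",
    "WeightTable",
    "WeightingError",
    "shuffle_sequence",
    "count_matches",
    "shuffle_background",
    "signal_to_noise",
    "compute_weights",
    "region_proportions",
    "load_bundled_weights",
    "DEFAULT_REFERENCE",
]

#: the canonical reference cell: 2t8A1 sites in 3'UTRs
DEFAULT_REFERENCE: tuple[SeedType, RegionKind] = (SeedType.T2t8A1, RegionKind.UTR3)

_TYPE_INDEX = {t: i for i, t in enumerate(SEED_TYPE_ORDER)}
_REGION_INDEX = {r: j for j, r in enumerate(REGION_ORDER)}


class WeightingError(ValueError):
    """Weight derivation is undefined for the given inputs."""


@dataclass
class CountMatrix:
    """5x4 seed-site counts indexed (SeedType, RegionKind).

    Integer-valued for observed corpora; real-valued when holding means
    over shuffle replicates.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((5, 4), dtype=float)
    )
    n_pairs: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (5, 4):
            raise ValueError(f"expected 5x4 counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def __getitem__(self, key: tuple[SeedType, RegionKind]) -> float:
        t, r = key
        return float(self.counts[_TYPE_INDEX[t], _REGION_INDEX[r]])

    def __setitem__(self, key: tuple[SeedType, RegionKind], value: float) -> None:
        t, r = key
        self.counts[_TYPE_INDEX[t], _REGION_INDEX[r]] = value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[t.value for t in SEED_TYPE_ORDER],
            columns=[r.value for r in REGION_ORDER],
        )


def _child_seed(seed: int, replicate: int, gene_id: str, region: RegionKind) -> int:
    """Stable per-(replicate, gene, region) seed so shuffles are independent
    of iteration order and of how pairs share genes."""
    digest = hashlib.sha256(
        f"{seed}\x1f{replicate}\x1f{gene_id}\x1f{region.value}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big")


def shuffle_sequence(seq: str, rng_seed: int) -> str:
    """Uniform random permutation of the sequence characters
    (mononucleotide shuffle); deterministic for a given seed."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    perm = np.random.default_rng(rng_seed).permutation(arr)
    return perm.tobytes().decode("ascii")


def count_matches(pairs: Sequence[tuple[MiRNA, GeneRegions]]) -> CountMatrix:
    """Total per-site counts of each (type, region) cell over a corpus of
    miRNA-gene pairs."""
    counts = np.zeros((5, 4), dtype=float)
    for mirna, gene in pairs:
        for region in REGION_ORDER:
            if region in gene:
                counts[:, _REGION_INDEX[region]] += count_sites_by_type(
                    mirna, gene[region]
                )
    return CountMatrix(counts=counts, n_pairs=len(pairs))


def shuffle_background(
    pairs: Sequence[tuple[MiRNA, GeneRegions]],
    n_shuffles: int = 50,
    rng_seed: int = 0,
) -> CountMatrix:
    """Mean per-cell counts over ``n_shuffles`` replicates in which every
    region sequence is independently mononucleotide-shuffled."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    total = np.zeros((5, 4), dtype=float)
    # Shuffle each distinct (gene, region) sequence once per replicate and
    # reuse it across pairs sharing the gene, mirroring a shuffled corpus.
    for rep in range(n_shuffles):
        cache: dict[tuple[str, RegionKind], np.ndarray] = {}
        for mirna, gene in pairs:
            for region in REGION_ORDER:
                if region not in gene:
                    continue
                key = (gene.gene_id, region)
                enc = cache.get(key)
                if enc is None:
                    shuffled = shuffle_sequence(
                        gene[region], _child_seed(rng_seed, rep, gene.gene_id, region)
                    )
                    enc = encode(shuffled)
                    cache[key] = enc
                total[:, _REGION_INDEX[region]] += count_sites_by_type(mirna, enc)
    return CountMatrix(counts=total / n_shuffles, n_pairs=len(pairs))


def signal_to_noise(observed: CountMatrix, background: CountMatrix) -> np.ndarray:
    """Per-cell SNR = observed / background.

    Cells with zero background are undefined (NaN) and excluded from
    weighting, with a warning.
    """
    snr = np.full((5, 4), np.nan)
    defined = background.counts > 0
    snr[defined] = observed.counts[defined] / background.counts[defined]
    if not defined.all():
        for t_idx, r_idx in zip(*np.nonzero(~defined)):
            warnings.warn(
                f"zero background for {SEED_TYPE_ORDER[t_idx].value}/"
                f"{REGION_ORDER[r_idx].value}: SNR undefined",
                stacklevel=2,
            )
    return snr


@dataclass
class WeightTable:
    """SNRs and derived weights for the 5 types x 4 regions grid."""

    snr: np.ndarray
    weights: np.ndarray
    reference: tuple[SeedType, RegionKind] = DEFAULT_REFERENCE

    def weight(self, seed_type: SeedType, region: RegionKind) -> float:
        w = float(self.weights[_TYPE_INDEX[seed_type], _REGION_INDEX[region]])
        if np.isnan(w):
            raise WeightingError(
                f"no weight defined for cell {seed_type.value}/{region.value}"
            )
        return w

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in SEED_TYPE_ORDER:
            for r in REGION_ORDER:
                rows.append(
                    {
                        "seed_type": t.value,
                        "region": r.value,
                        "snr": self.snr[_TYPE_INDEX[t], _REGION_INDEX[r]],
                        "weight": self.weights[_TYPE_INDEX[t], _REGION_INDEX[r]],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeightTable":
        snr = np.full((5, 4), np.nan)
        weights = np.full((5, 4), np.nan)
        for _, row in df.iterrows():
            t = _TYPE_INDEX[SeedType.from_name(str(row["seed_type"]))]
            r = _REGION_INDEX[RegionKind.from_name(str(row["region"]))]
            if "snr" in df.columns:
                snr[t, r] = float(row["snr"])
            weights[t, r] = float(row["weight"])
        ref_t, ref_r = DEFAULT_REFERENCE
        return cls(snr=snr, weights=weights)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))


def compute_weights(
    snr: np.ndarray,
    reference: tuple[SeedType, RegionKind] | str = DEFAULT_REFERENCE,
) -> WeightTable:
    """Convert an SNR grid to weights, W_ij = (SNR_ij - 1)/(SNR_ref - 1).

    ``reference`` may be a (type, region) cell or ``"auto"`` to use the
    cell with the largest defined SNR — the rationale behind the canonical
    default, which is the empirically strongest cell in genome-wide
    verified corpora.  The reference cell gets weight 1 exactly; cells with
    SNR < 1 are clamped to 0 (depletion carries no positive evidence);
    undefined (NaN) cells stay undefined.
    """
    snr = np.asarray(snr, dtype=float)
    if snr.shape != (5, 4):
        raise ValueError(f"expected 5x4 SNR grid, got {snr.shape}")
    if isinstance(reference, str):
        if reference != "auto":
            raise ValueError("reference must be a (type, region) cell or 'auto'")
        if np.isnan(snr).all():
            raise WeightingError("all SNR cells undefined")
        t_idx, r_idx = np.unravel_index(np.nanargmax(snr), snr.shape)
        reference = (SEED_TYPE_ORDER[t_idx], REGION_ORDER[r_idx])
    ref_t, ref_r = reference
    snr_ref = snr[_TYPE_INDEX[ref_t], _REGION_INDEX[ref_r]]
    if np.isnan(snr_ref) or snr_ref <= 1.0:
        raise WeightingError(
            f"reference cell {ref_t.value}/{ref_r.value} has SNR "
            f"{snr_ref:.4g} <= 1; weighting is undefined"
        )
    weights = (snr - 1.0) / (snr_ref - 1.0)
    clamped = weights < 0
    if clamped.any():
        warnings.warn(
            f"{int(np.count_nonzero(clamped))} cell(s) with SNR < 1 clamped "
            "to weight 0",
            stacklevel=2,
        )
        weights[clamped] = 0.0
    weights[_TYPE_INDEX[ref_t], _REGION_INDEX[ref_r]] = 1.0
    return WeightTable(snr=snr, weights=weights, reference=reference)


def region_proportions(observed: CountMatrix) -> np.ndarray:
    """Within-region fractions of the five site types (4 regions x 5
    types; each defined row sums to 1).  Zero rows are NaN with a warning."""
    out = np.full((4, 5), np.nan)
    by_region = observed.counts.T  # 4x5
    sums = by_region.sum(axis=1)
    for j, total in enumerate(sums):
        if total > 0:
            out[j] = by_region[j] / total
        else:
            warnings.warn(
                f"no sites in region {REGION_ORDER[j].value}: proportions "
                "undefined",
                stacklevel=2,
            )
    return out


def load_bundled_weights() -> WeightTable:
    """Load the packaged weight table derived from a genome-wide corpus of
    experimentally verified human miRNA-gene pairs (655 miRNAs, shuffled
    background of 50 replicates).  Usable without any corpus of one's own."""
    with resources.files("mirspan.data").joinpath("default_weights.tsv").open() as fh:
        return WeightTable.from_frame(pd.read_csv(fh, sep="\t", comment="#"))


def load_bundled_counts() -> tuple[CountMatrix, CountMatrix]:
    """Observed and shuffle-mean counts behind the bundled weight table."""
    with resources.files("mirspan.data").joinpath("verified_pair_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    obs = CountMatrix()
    bg = CountMatrix()
    for _, row in df.iterrows():
        key = (
            SeedType.from_name(str(row["seed_type"])),
            RegionKind.from_name(str(row["region"])),
        )
        obs[key] = float(row["observed"])
        bg[key] = float(row["background_mean"])
    return obs, bg
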