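"""Seed-match scanning: find and type all seed sites of a miRNA in a gene.

Five site types are recognised, four canonical and one non-canonical:

================  =============================================  ==========
type              definition                                     site span
================  =============================================  ==========
``2t8A1``         Watson-Crick pairing of miRNA positions 2-8    8 nt
                  and an adenine in the target opposite
                  miRNA position 1
``2t8``           Watson-Crick pairing of positions 2-8          7 nt
``2t7A1``         Watson-Crick pairing of positions 2-7 plus     7 nt
                  the opposite-position-1 adenine
``2t7``           Watson-Crick pairing of positions 2-7          6 nt
``1t8GU``         positions 1-8 all paired, with exactly one     8 nt
                  G:U wobble and seven Watson-Crick pairs
================  =============================================  ==========

Classification is per 8-nt target frame: the frame's 3'-most nucleotide
lies opposite miRNA position 1 (duplexes are antiparallel, so target
position ``k`` in a window of length ``L`` pairs miRNA position
``L+1-k``).  Every frame is assigned at most one type, by decreasing
stringency 2t8A1 > 2t8 > 2t7A1 > 2t7, with 1t8GU only when no canonical
type applies; this keeps per-type counts disjoint.  N never pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .seqmodel import GeneRegions, MiRNA, REGION_ORDER, RegionKind

__all__ = [
    "SeedType",
    "SeedSite",
    "site_pairs_wc",
    "classify_window",
    "scan_sites",
    "count_sites_by_type",
    "SEED_TYPE_ORDER",
]


class SeedType(enum.Enum):
    T2t8A1 = "2t8A1"
    T2t8 = "2t8"
    T2t7A1 = "2t7A1"
    T2t7 = "2t7"
    T1t8GU = "1t8GU"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "SeedType":
        for t in cls:
            if t.value == name:
                return t
        raise ValueError(f"unknown seed type {name!r}")


SEED_TYPE_ORDER = tuple(SeedType)

#: length of the reported site span per type
SITE_LENGTH = {
    SeedType.T2t8A1: 8,
    SeedType.T2t8: 7,
    SeedType.T2t7A1: 7,
    SeedType.T2t7: 6,
    SeedType.T1t8GU: 8,
}

# offset of the reported span start within the 8-nt frame: the 6/7-nt types
# exclude frame positions their definition does not constrain
_SPAN_START_IN_FRAME = {
    SeedType.T2t8A1: 0,
    SeedType.T2t8: 0,
    SeedType.T2t7A1: 1,
    SeedType.T2t7: 1,
    SeedType.T1t8GU: 0,
}


@dataclass(frozen=True)
class SeedSite:
    """One typed seed-match occurrence on a region sequence.

    ``start``/``end`` are 0-based half-open offsets on the region sequence
    read 5'->3' (BED-like).  ``wobble_pos`` is the miRNA position (1-8) of
    the single G:U pair and is present only for 1t8GU sites.
    """

    gene_id: str
    region: RegionKind
    start: int
    end: int
    seed_type: SeedType
    wobble_pos: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LENGTH[self.seed_type]:
            raise ValueError(
                f"span [{self.start},{self.end}) inconsistent with type "
                f"{self.seed_type}"
            )
        if (self.wobble_pos is not None) != (self.seed_type is SeedType.T1t8GU):
            raise ValueError("wobble_pos present iff seed_type is 1t8GU")


# ---------------------------------------------------------------------------
# pairing tables
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}

# boolean lookup tables indexed [miRNA base, target base]
_WC_TABLE = np.zeros((5, 5), dtype=bool)
_GU_TABLE = np.zeros((5, 5), dtype=bool)
for (a, b) in _WC:
    _WC_TABLE[_BASE_INDEX[a], _BASE_INDEX[b]] = True
for (a, b) in _GU:
    _GU_TABLE[_BASE_INDEX[a], _BASE_INDEX[b]] = True


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as an int8 array (A,C,G,U,N -> 0..4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for ch, idx in _BASE_INDEX.items():
        out[arr == ord(ch)] = idx
    if (out < 0).any():
        bad = int(np.argmax(out < 0))
        raise ValueError(f"unencodable character {seq[bad]!r} at offset {bad}")
    return out


def site_pairs_wc(mirna_window: str, target_window: str) -> bool:
    """True iff the two equal-length windows form a perfect Watson-Crick
    duplex under the antiparallel convention (both given 5'->3'; target
    position k pairs miRNA position L+1-k).  Any N fails."""
    if len(mirna_window) != len(target_window):
        raise ValueError(
            f"length mismatch: {len(mirna_window)} vs {len(target_window)}"
        )
    return all(
        (m, t) in _WC for m, t in zip(mirna_window, reversed(target_window))
    )


def classify_window(mirna: MiRNA, target8: str) -> tuple[SeedType, int | None] | None:
    """Classify one 8-nt target frame against a miRNA's seed.

    ``target8`` is given 5'->3'; its last nucleotide lies opposite miRNA
    position 1.  Returns ``(seed_type, wobble_pos)`` for the unique most
    stringent applicable type, or None.
    """
    if len(target8) != 8:
        raise ValueError(f"target frame must be 8 nt, got {len(target8)}")
    m = mirna.seed
    # pair class per miRNA position p = 1..8 (target8[8-p] opposes p)
    wc = [(m[p - 1], target8[8 - p]) in _WC for p in range(1, 9)]
    gu = [(m[p - 1], target8[8 - p]) in _GU for p in range(1, 9)]
    a1 = target8[7] == "A"
    wc27 = all(wc[1:7])
    if wc27 and wc[7]:
        return (SeedType.T2t8A1, None) if a1 else (SeedType.T2t8, None)
    if wc27:
        return (SeedType.T2t7A1, None) if a1 else (SeedType.T2t7, None)
    paired = [w or g for w, g in zip(wc, gu)]
    if all(paired) and sum(gu) == 1:
        return SeedType.T1t8GU, gu.index(True) + 1
    return None


def _frame_types(seed8: np.ndarray, region: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised frame classification.

    Parameters are int8-encoded sequences (miRNA seed of length 8, region
    of length L).  Returns ``(type_codes, wobble_pos)`` over the L-7
    frames: type code is the index into ``SEED_TYPE_ORDER`` or -1, and
    wobble_pos the 1-based miRNA wobble position (0 where absent).
    """
    n_off = len(region) - 8 + 1
    if n_off <= 0:
        return (np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int8))
    wc = np.empty((8, n_off), dtype=bool)
    gu = np.empty((8, n_off), dtype=bool)
    for p in range(1, 9):  # target base opposite position p is region[off+8-p]
        t = region[8 - p : 8 - p + n_off]
        wc[p - 1] = _WC_TABLE[seed8[p - 1], t]
        gu[p - 1] = _GU_TABLE[seed8[p - 1], t]
    a1 = region[7 : 7 + n_off] == _BASE_INDEX["A"]
    wc27 = wc[1:7].all(axis=0)
    wc28 = wc27 & wc[7]
    paired = wc | gu
    one_gu = paired.all(axis=0) & (gu.sum(axis=0) == 1)

    codes = np.full(n_off, -1, dtype=np.int8)
    codes[one_gu & ~wc27] = SEED_TYPE_ORDER.index(SeedType.T1t8GU)
    codes[wc27 & ~wc[7] & ~a1] = SEED_TYPE_ORDER.index(SeedType.T2t7)
    codes[wc27 & ~wc[7] & a1] = SEED_TYPE_ORDER.index(SeedType.T2t7A1)
    codes[wc28 & ~a1] = SEED_TYPE_ORDER.index(SeedType.T2t8)
    codes[wc28 & a1] = SEED_TYPE_ORDER.index(SeedType.T2t8A1)

    wob = np.zeros(n_off, dtype=np.int8)
    mask = codes == SEED_TYPE_ORDER.index(SeedType.T1t8GU)
    if mask.any():
        wob[mask] = 1 + gu[:, mask].argmax(axis=0)
    return codes, wob


def count_sites_by_type(mirna: MiRNA, region_seq: str | np.ndarray) -> np.ndarray:
    """Count seed sites of each of the five types in one region sequence.

    Returns an int64 vector ordered as ``SEED_TYPE_ORDER``.  This is the
    fast path used for corpus-scale counting; it agrees with
    :func:`scan_sites` by construction (same classification core).
    """
    enc = region_seq if isinstance(region_seq, np.ndarray) else encode(region_seq)
    codes, _ = _frame_types(encode(mirna.seed), enc)
    return np.bincount(codes[codes >= 0], minlength=5).astype(np.int64)


def scan_sites(mirna: MiRNA, gene: GeneRegions) -> list[SeedSite]:
    """Find every typed seed-match site of ``mirna`` in every present
    region of ``gene``; sorted by (region, start, end)."""
    sites: list[SeedSite] = []
    seed8 = encode(mirna.seed)
    for region in REGION_ORDER:
        if region not in gene:
            continue
        codes, wob = _frame_types(seed8, encode(gene[region]))
        for off in np.flatnonzero(codes >= 0):
            stype = SEED_TYPE_ORDER[codes[off]]
            start = int(off) + _SPAN_START_IN_FRAME[stype]
            sites.append(
                SeedSite(
                    gene_id=gene.gene_id,
                    region=region,
                    start=start,
                    end=start + SITE_LENGTH[stype],
                    seed_type=stype,
                    wobble_pos=int(wob[off]) if stype is SeedType.T1t8GU else None,
                )
            )
    region_rank = {r: i for i, r in enumerate(REGION_ORDER)}
    sites.sort(key=lambda s: (region_rank[s.region], s.start, s.end, s.seed_type.value))
    return sites
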