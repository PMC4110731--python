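"""Synthetic corpora with planted seed sites and controlled enrichment.

The generator emulates the shape of a verified-interaction corpus: a set
of miRNAs, a set of genes with i.i.d. background sequences for the four
regions, and a pair list.  Seed sites of chosen types are planted at
recorded positions; because a site's type is fully determined by its 8-nt
target frame and the generator writes that entire frame, every planted
site is recovered by the scanner with exactly its planted type (no
stronger type can absorb it).  A truth ledger lists every planted site.

Enrichment of one (type, region) cell is expressed relative to the
analytic background expectation: with enrichment factor f, each pair
receives on average (f-1) x E[background sites] extra planted sites in
that cell, so observed/background counts concentrate near f.

Region lengths default to 4,000 nt each.  Real 5'UTRs are far shorter;
the uniform length is chosen so that even the rarest site class has
double-digit expected background counts at the default corpus size, which
SNR estimation needs.  The generator makes no attempt to mimic genomic
dinucleotide statistics or isoform structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seedscan import SeedSite, SeedType, SITE_LENGTH, classify_window
from .seqmodel import GeneRegions, MiRNA, REGION_ORDER, RegionKind, write_fasta

__all__ = [
    "SynthSpec",
    "SynthCorpus",
    "PlantedSite",
    "generate_corpus",
    "expected_background_sites",
    "write_corpus",
    "GenerationError",
]

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {"G": "U", "U": "G"}
_BASES = "ACGU"


class GenerationError(ValueError):
    """The requested corpus cannot be generated (e.g. region too short)."""


@dataclass
class SynthSpec:
    """Parameters of a synthetic corpus.

    ``planted_sites`` plants a fixed (possibly fractional, realised by a
    Bernoulli draw) number of sites per pair in given cells;
    ``enriched_cell``/``enrichment_factor`` instead plants the number that
    makes the cell's observed/background ratio concentrate near the
    factor.  One pair is formed per gene, cycling through the miRNAs.
    """

    n_mirnas: int = 20
    n_genes: int = 200
    mirna_length: int = 22
    region_lengths: dict[RegionKind, int] = field(
        default_factory=lambda: {r: 4000 for r in REGION_ORDER}
    )
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_sites: list[tuple[SeedType, RegionKind, float]] = field(
        default_factory=list
    )
    enriched_cell: tuple[SeedType, RegionKind] | None = None
    enrichment_factor: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if min(self.composition) < 0:
            raise ValueError("composition must be nonnegative")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        for r, L in self.region_lengths.items():
            if L < 60:
                raise ValueError(
                    f"region {r.value} length {L} < 60; full context windows "
                    "must fit"
                )
        for _, _, count in self.planted_sites:
            if count < 0:
                raise ValueError("planted counts must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    """Truth-ledger entry for one planted site."""

    mirna_id: str
    gene_id: str
    region: RegionKind
    frame_start: int  # 8-nt frame offset on the region
    site_start: int   # reported span, as the scanner emits it
    site_end: int
    seed_type: SeedType


@dataclass
class SynthCorpus:
    mirnas: list[MiRNA]
    genes: dict[str, GeneRegions]
    pairs: list[tuple[str, str]]  # (mirna_id, gene_id)
    ledger: list[PlantedSite]


def _site_probability(seed: str, seed_type: SeedType, comp: dict[str, float]) -> float:
    """Probability that a random i.i.d. 8-nt frame classifies as
    ``seed_type`` for a miRNA with the given seed (positions 1-8)."""
    q = comp
    wc = [q[_WC[seed[p - 1]]] for p in range(1, 9)]  # P(WC at position p)
    pA = q["A"]
    p27 = float(np.prod(wc[1:7]))
    if seed_type is SeedType.T2t8A1:
        return p27 * wc[7] * pA
    if seed_type is SeedType.T2t8:
        return p27 * wc[7] * (1.0 - pA)
    if seed_type is SeedType.T2t7A1:
        return p27 * (1.0 - wc[7]) * pA
    if seed_type is SeedType.T2t7:
        return p27 * (1.0 - wc[7]) * (1.0 - pA)
    # 1t8GU: exactly one wobble, at a position in 2..7 (a wobble at 1 or 8
    # leaves positions 2-7 Watson-Crick and is absorbed by a canonical type)
    total = 0.0
    for p in range(2, 8):
        base = seed[p - 1]
        if base in _WOBBLE:
            others = [wc[k - 1] for k in range(1, 9) if k != p]
            total += q[_WOBBLE[base]] * float(np.prod(others))
    return total


def expected_background_sites(
    mirna: MiRNA,
    seed_type: SeedType,
    region_length: int,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Expected number of sites of ``seed_type`` in one i.i.d. random
    region sequence (the shuffle-null expectation)."""
    comp = dict(zip(_BASES, composition))
    n_frames = max(0, region_length - 8 + 1)
    return n_frames * _site_probability(mirna.seed, seed_type, comp)


def _build_frame(seed: str, seed_type: SeedType, rng: np.random.Generator) -> str:
    """Construct an 8-nt target frame that classifies exactly as
    ``seed_type`` (frame position 8-p opposes miRNA position p)."""
    t = [None] * 8  # type: list[str | None]

    def set_wc(p: int) -> None:
        t[8 - p] = _WC[seed[p - 1]]

    if seed_type in (SeedType.T2t8A1, SeedType.T2t8):
        for p in range(2, 9):
            set_wc(p)
        t[7] = "A" if seed_type is SeedType.T2t8A1 else rng.choice(list("CGU"))
    elif seed_type in (SeedType.T2t7A1, SeedType.T2t7):
        for p in range(2, 8):
            set_wc(p)
        t[0] = rng.choice([b for b in _BASES if b != _WC[seed[7]]])
        t[7] = "A" if seed_type is SeedType.T2t7A1 else rng.choice(list("CGU"))
    else:  # 1t8GU
        options = [p for p in range(2, 8) if seed[p - 1] in _WOBBLE]
        if not options:
            raise GenerationError(
                "miRNA seed has no G/U at positions 2-7; a 1t8GU site "
                "cannot be planted"
            )
        p_wob = int(rng.choice(options))
        for p in range(1, 9):
            set_wc(p)
        t[8 - p_wob] = _WOBBLE[seed[p_wob - 1]]
    frame = "".join(b if b is not None else rng.choice(list(_BASES)) for b in t)
    return frame


def _random_seq(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


def generate_corpus(spec: SynthSpec) -> SynthCorpus:
    """Generate a reproducible corpus per ``spec`` (see class docstring)."""
    rng = np.random.default_rng(spec.rng_seed)
    probs = np.asarray(spec.composition, dtype=float)

    mirnas: list[MiRNA] = []
    for k in range(spec.n_mirnas):
        while True:
            seq = _random_seq(rng, spec.mirna_length, probs)
            # keep every miRNA 1t8GU-plantable: need G/U in seed 2..7
            if any(b in "GU" for b in seq[1:7]):
                break
        mirnas.append(MiRNA(id=f"mir-{k:03d}", sequence=seq))

    genes: dict[str, GeneRegions] = {}
    pairs: list[tuple[str, str]] = []
    ledger: list[PlantedSite] = []

    for g in range(spec.n_genes):
        gene_id = f"gene-{g:04d}"
        mirna = mirnas[g % spec.n_mirnas]
        regions: dict[RegionKind, list[str]] = {
            r: list(_random_seq(rng, L, probs))
            for r, L in spec.region_lengths.items()
        }

        # assemble the planting plan for this pair
        plan: list[tuple[SeedType, RegionKind, int]] = []
        for stype, region, count in spec.planted_sites:
            n = int(count) + (1 if rng.random() < count - int(count) else 0)
            plan.append((stype, region, n))
        if spec.enriched_cell is not None and spec.enrichment_factor > 1.0:
            stype, region = spec.enriched_cell
            mean = (spec.enrichment_factor - 1.0) * expected_background_sites(
                mirna, stype, spec.region_lengths[region], spec.composition
            )
            n = int(mean) + (1 if rng.random() < mean - int(mean) else 0)
            plan.append((stype, region, n))

        occupied: dict[RegionKind, list[tuple[int, int]]] = {
            r: [] for r in regions
        }
        for stype, region, n in plan:
            if region not in regions:
                raise GenerationError(
                    f"cannot plant in absent region {region.value}"
                )
            L = spec.region_lengths[region]
            for _ in range(n):
                frame = _build_frame(mirna.seed, stype, rng)
                placed = False
                for _attempt in range(200):
                    off = int(rng.integers(0, L - 8 + 1))
                    if all(
                        off + 8 <= s or off >= e for s, e in occupied[region]
                    ):
                        occupied[region].append((off, off + 8))
                        regions[region][off : off + 8] = list(frame)
                        placed = True
                        break
                if not placed:
                    raise GenerationError(
                        f"region {region.value} (length {L}) too short to "
                        f"host the requested sites"
                    )
                got = classify_window(mirna, frame)
                assert got is not None and got[0] is stype, "frame construction bug"
                span0 = off if stype not in (SeedType.T2t7, SeedType.T2t7A1) else off + 1
                ledger.append(
                    PlantedSite(
                        mirna_id=mirna.id,
                        gene_id=gene_id,
                        region=region,
                        frame_start=off,
                        site_start=span0,
                        site_end=span0 + SITE_LENGTH[stype],
                        seed_type=stype,
                    )
                )

        genes[gene_id] = GeneRegions(
            gene_id, {r: "".join(chars) for r, chars in regions.items()}
        )
        pairs.append((mirna.id, gene_id))

    return SynthCorpus(mirnas=mirnas, genes=genes, pairs=pairs, ledger=ledger)


def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write a corpus as plain files: miRNA FASTA, one FASTA per region,
    a pair TSV and the truth-ledger TSV.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["mirna"] = out / "mirnas.fasta"
    write_fasta(paths["mirna"], [(m.id, m.sequence) for m in corpus.mirnas])

    for region in REGION_ORDER:
        records = [
            (gid, gene[region])
            for gid, gene in corpus.genes.items()
            if region in gene
        ]
        if records:
            paths[region.value] = out / f"{region.value}.fasta"
            write_fasta(paths[region.value], records)

    paths["pairs"] = out / "pairs.tsv"
    with open(paths["pairs"], "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mirna_id, gene_id in corpus.pairs:
            fh.write(f"{mirna_id}\t{gene_id}\n")

    paths["ledger"] = out / "planted_sites.tsv"
    with open(paths["ledger"], "w") as fh:
        fh.write(
            "mirna_id\tgene_id\tregion\tframe_start\tsite_start\tsite_end\tseed_type\n"
        )
        for p in corpus.ledger:
            fh.write(
                f"{p.mirna_id}\t{p.gene_id}\t{p.region.value}\t{p.frame_start}\t"
                f"{p.site_start}\t{p.site_end}\t{p.seed_type.value}\n"
            )
    return paths
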