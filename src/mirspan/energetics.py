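"""Thermodynamics of candidate sites: duplex and accessibility energies.

For every seed-match site three quantities are computed on a local context
window (up to 30 nt of 5' flank + the site + up to 20 nt of 3' flank, i.e.
58 nt for an 8-nt site away from region ends):

``dG_duplex``
    Minimum free energy of hybridising the full miRNA against the window,
    intramolecular pairing forbidden — the defining property of a
    hybridization (as opposed to cofolding) model.  Watson-Crick and G:U
    pairs are allowed; consecutive pairs are scored by nearest-neighbor
    stacking terms, interruptions by affine bulge / internal-loop
    penalties, plus a duplex initiation term.  The empty duplex has energy
    0, so reported values are always <= 0.

``dG_open``
    Cost of making the site accessible: the increase in the window's
    intramolecular folding MFE when the site nucleotides are forced to be
    unpaired.  Always >= 0.

``ddG``
    The accessibility-corrected stability, dG_duplex - dG_open.

Both engines are exact dynamic programs over a reduced nearest-neighbor
parameter set (Turner-style Watson-Crick stacks; pooled values for stacks
involving G:U; linear loop penalties).  The folding DP is a standard
Zuker-style recursion with hairpins, stacks, bulges, internal loops
(bounded size) and multiloops with affine cost.  Absolute energies are
therefore model-specific; comparisons are meaningful within one parameter
set, and an adapter to an external thermodynamic library can be plugged in
for parity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .seedscan import SeedSite
from .seqmodel import RegionKind

__all__ = [
    "EnergyParams",
    "SiteWindow",
    "SiteEnergies",
    "extract_window",
    "duplex_energy",
    "opening_energy",
    "fold_mfe",
    "site_energies",
    "load_default_params",
]

_BASES = "ACGUN"
_IDX = {b: i for i, b in enumerate(_BASES)}
_ALLOWED_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_PAIRABLE = [[False] * 5 for _ in range(5)]
for a, b in _ALLOWED_PAIRS:
    _PAIRABLE[_IDX[a]][_IDX[b]] = True

INF = math.inf


@dataclass
class EnergyParams:
    """Nearest-neighbor parameter set (kcal/mol at 37 C).

    ``stack[a][b][c][d]`` is the stacking term for inner pair (c,d)
    stacked on outer pair (a,b), where a/c sit on one strand 5'->3' and
    b/d on the other 3'->5' (the classic 5'ac3'/3'bd5' quartet); +inf
    where either duo is not a legal pair.
    """

    version: str = "unnamed"
    duplex_init: float = 0.0
    hairpin_init: float = 5.4
    hairpin_per_nt: float = 0.3
    bulge_init: float = 3.8
    bulge_per_nt: float = 0.4
    internal_init: float = 4.0
    internal_per_nt: float = 0.35
    multi_init: float = 3.4
    multi_branch: float = 0.4
    multi_unpaired: float = 0.0
    min_hairpin: int = 3
    max_loop: int = 15
    stack: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stack:
            self.stack = [
                [[[INF] * 5 for _ in range(5)] for _ in range(5)] for _ in range(5)
            ]

    def set_stack(self, key: str, value: float) -> None:
        """Set a stack term from 'XY/ZW' notation (strand1 5'->3' XY,
        strand2 3'->5' ZW) and its symmetry partner."""
        duo1, duo2 = key.split("/")
        (x, y), (z, w) = duo1, duo2
        if (x, z) not in _ALLOWED_PAIRS or (y, w) not in _ALLOWED_PAIRS:
            raise ValueError(f"stack {key!r} involves a non-pairing duo")
        a, b, c, d = _IDX[x], _IDX[z], _IDX[y], _IDX[w]
        self.stack[a][b][c][d] = value
        self.stack[d][c][b][a] = value  # 180-degree rotation symmetry

    def fill_gu_stacks(self, one_gu: float, two_gu: float) -> None:
        """Pooled values for stacks involving G:U pairs not set explicitly."""
        gu = {(_IDX["G"], _IDX["U"]), (_IDX["U"], _IDX["G"])}
        for (a, b) in [(_IDX[x], _IDX[y]) for x, y in _ALLOWED_PAIRS]:
            for (c, d) in [(_IDX[x], _IDX[y]) for x, y in _ALLOWED_PAIRS]:
                n_gu = ((a, b) in gu) + ((c, d) in gu)
                if n_gu and self.stack[a][b][c][d] == INF:
                    self.stack[a][b][c][d] = one_gu if n_gu == 1 else two_gu

    @classmethod
    def uniform(
        cls,
        stack: float = -3.0,
        loop_per_nt: float = 4.0,
        *,
        duplex_init: float = 0.0,
        hairpin_init: float = 0.0,
    ) -> "EnergyParams":
        """A deliberately simple parameter set (every stack equal, linear
        loops, no initiation) for analytically tractable test cases."""
        p = cls(
            version="uniform-toy",
            duplex_init=duplex_init,
            hairpin_init=hairpin_init,
            hairpin_per_nt=loop_per_nt,
            bulge_init=0.0,
            bulge_per_nt=loop_per_nt,
            internal_init=0.0,
            internal_per_nt=loop_per_nt,
            multi_init=0.0,
            multi_branch=0.0,
            multi_unpaired=loop_per_nt,
        )
        for (x, z) in _ALLOWED_PAIRS:
            for (y, w) in _ALLOWED_PAIRS:
                p.set_stack(f"{x}{y}/{z}{w}", stack)
        return p

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergyParams":
        """Read a parameter file: TSV with columns kind/key/value, kinds
        ``meta`` (version), ``scalar`` and ``stack`` ('XY/ZW' keys)."""
        p = cls()
        gu_pool: dict[str, float] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#") or line.startswith("kind\t"):
                    continue
                kind, key, value = line.split("\t")
                if kind == "meta" and key == "version":
                    p.version = value
                elif kind == "scalar":
                    if key in ("gu_stack", "gugu_stack"):
                        gu_pool[key] = float(value)
                    elif key in ("min_hairpin", "max_loop"):
                        setattr(p, key, int(value))
                    else:
                        setattr(p, key, float(value))
                elif kind == "stack":
                    p.set_stack(key, float(value))
                else:
                    raise ValueError(f"unknown parameter kind {kind!r}")
        if gu_pool:
            p.fill_gu_stacks(
                gu_pool.get("gu_stack", -1.2), gu_pool.get("gugu_stack", -0.4)
            )
        return p


def load_default_params() -> EnergyParams:
    """The bundled reduced nearest-neighbor parameter set."""
    path = resources.files("mirspan.data").joinpath("energy_params_reduced_v1.tsv")
    with resources.as_file(path) as p:
        return EnergyParams.from_tsv(p)


@dataclass(frozen=True)
class SiteWindow:
    """Local sequence context of one seed site, with the site's position
    re-expressed in window coordinates (half-open)."""

    sequence: str
    site_start: int
    site_end: int
    gene_id: str = ""
    region: RegionKind | None = None
    region_offset: int = 0  # window start on the region sequence

    def __post_init__(self) -> None:
        if not (0 <= self.site_start < self.site_end <= len(self.sequence)):
            raise ValueError("site span outside window")


@dataclass(frozen=True)
class SiteEnergies:
    dG_duplex: float
    dG_open: float

    @property
    def ddG(self) -> float:
        return self.dG_duplex - self.dG_open


#: flank lengths around the site (5', 3')
FLANK_5P = 30
FLANK_3P = 20


def extract_window(region_seq: str, site: SeedSite) -> SiteWindow:
    """Cut the site's context window: up to 30 nt upstream + site + up to
    20 nt downstream, truncated at region ends (58 nt for an interior
    8-nt site)."""
    if site.end > len(region_seq):
        raise ValueError("site outside region sequence")
    wstart = max(0, site.start - FLANK_5P)
    wend = min(len(region_seq), site.end + FLANK_3P)
    return SiteWindow(
        sequence=region_seq[wstart:wend],
        site_start=site.start - wstart,
        site_end=site.end - wstart,
        gene_id=site.gene_id,
        region=site.region,
        region_offset=wstart,
    )


def _enc(seq: str) -> list[int]:
    return [_IDX[c] for c in seq]


def duplex_energy(mirna_seq: str, window: SiteWindow | str, params: EnergyParams) -> float:
    """Hybridization MFE of the full miRNA against the window.

    Intramolecular pairs are forbidden; the pair list is antiparallel and
    monotone.  Returns min(0, duplex_init + best interaction), so a window
    offering no favourable duplex scores 0.
    """
    y_seq = window.sequence if isinstance(window, SiteWindow) else window
    x = _enc(mirna_seq)
    y = _enc(y_seq)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both strands must be at least 2 nt")
    n, m = len(x), len(y)
    maxl = params.max_loop
    st = params.stack
    # E[i][j]: best energy of a duplex whose 3'-most pair on x is (i, j)
    E = [[INF] * m for _ in range(n)]
    best = INF
    for i in range(n):
        xi = x[i]
        row = _PAIRABLE[xi]
        for j in range(m):
            if not row[y[j]]:
                continue
            e = 0.0  # (i,j) opens the duplex
            for pi in range(max(0, i - maxl - 1), i):
                Epi = E[pi]
                gap_x = i - pi - 1
                for pj in range(j + 1, min(m, j + maxl + 2 - gap_x)):
                    prev = Epi[pj]
                    if prev == INF:
                        continue
                    gap_y = pj - j - 1
                    if gap_x == 0 and gap_y == 0:
                        cand = prev + st[x[pi]][y[pj]][xi][y[j]]
                    elif gap_x == 0 or gap_y == 0:
                        cand = prev + params.bulge_init + params.bulge_per_nt * (
                            gap_x + gap_y
                        )
                    else:
                        cand = prev + params.internal_init + params.internal_per_nt * (
                            gap_x + gap_y
                        )
                    if cand < e:
                        e = cand
            E[i][j] = e
            if e < best:
                best = e
    if best == INF:
        return 0.0
    return min(0.0, params.duplex_init + best)


def fold_mfe(
    seq: str,
    params: EnergyParams,
    forced_unpaired: Sequence[int] = (),
) -> float:
    """Intramolecular folding MFE of ``seq`` (<= 0; the open chain scores
    0).  Positions listed in ``forced_unpaired`` may not pair.

    Zuker-style recursion: C (energy closed by a pair) via hairpin,
    stack/bulge/internal loop (size-capped) or multiloop; M / M1 for
    multiloop segments; F for the exterior.
    """
    s = _enc(seq)
    n = len(s)
    blocked = [False] * n
    for k in forced_unpaired:
        blocked[k] = True

    def pairable(i: int, j: int) -> bool:
        return (
            _PAIRABLE[s[i]][s[j]]
            and not blocked[i]
            and not blocked[j]
            and j - i - 1 >= params.min_hairpin
        )

    C = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]   # >=1 multiloop branch in s[i..j]
    M1 = [[INF] * n for _ in range(n)]  # exactly 1 branch, starting at i

    for span in range(params.min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- C ---
            if pairable(i, j):
                size = j - i - 1
                e = params.hairpin_init + params.hairpin_per_nt * max(
                    0, size - params.min_hairpin
                )
                # interior: inner pair (p, q)
                for p in range(i + 1, min(j - 1, i + params.max_loop + 2)):
                    g1 = p - i - 1
                    for q in range(max(p + 1, j - 1 - (params.max_loop - g1)), j):
                        cpq = C[p][q]
                        if cpq == INF:
                            continue
                        g2 = j - q - 1
                        if g1 == 0 and g2 == 0:
                            cand = params.stack[s[i]][s[j]][s[p]][s[q]] + cpq
                        elif g1 == 0 or g2 == 0:
                            cand = (
                                params.bulge_init
                                + params.bulge_per_nt * (g1 + g2)
                                + cpq
                            )
                        else:
                            cand = (
                                params.internal_init
                                + params.internal_per_nt * (g1 + g2)
                                + cpq
                            )
                        if cand < e:
                            e = cand
                # multiloop closure: >=2 branches inside
                for k in range(i + 2, j - 1):
                    if M[i + 1][k - 1] != INF and M1[k][j - 1] != INF:
                        cand = (
                            params.multi_init
                            + params.multi_branch
                            + M[i + 1][k - 1]
                            + M1[k][j - 1]
                        )
                        if cand < e:
                            e = cand
                C[i][j] = e
            # --- M1: one branch whose helix starts at i ---
            e = INF
            if C[i][j] != INF:
                e = C[i][j] + params.multi_branch
            if j > i and M1[i][j - 1] != INF:
                e = min(e, M1[i][j - 1] + params.multi_unpaired)
            M1[i][j] = e
            # --- M: >=1 branch anywhere in [i..j] ---
            e = M1[i][j]
            if j > i and M[i + 1][j] != INF:
                e = min(e, M[i + 1][j] + params.multi_unpaired)
            for k in range(i + 1, j):
                if M[i][k - 1] != INF and M1[k][j] != INF:
                    e = min(e, M[i][k - 1] + M1[k][j])
            M[i][j] = e

    # exterior loop
    F = [0.0] * (n + 1)  # F[k]: MFE of s[0..k-1]
    for k in range(1, n + 1):
        best = F[k - 1]
        j = k - 1
        for i in range(0, j):
            if C[i][j] != INF:
                cand = F[i] + C[i][j]
                if cand < best:
                    best = cand
        F[k] = best
    return min(0.0, F[n])


def opening_energy(window: SiteWindow, params: EnergyParams) -> float:
    """dG_open: MFE with site nucleotides forced unpaired minus the
    unconstrained MFE.  Nonnegative by construction."""
    unconstrained = fold_mfe(window.sequence, params)
    constrained = fold_mfe(
        window.sequence, params, forced_unpaired=range(window.site_start, window.site_end)
    )
    return max(0.0, constrained - unconstrained)


def site_energies(mirna_seq: str, window: SiteWindow, params: EnergyParams) -> SiteEnergies:
    """Assemble dG_duplex, dG_open (and thereby ddG) for one site."""
    return SiteEnergies(
        dG_duplex=duplex_energy(mirna_seq, window, params),
        dG_open=opening_energy(window, params),
    )
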