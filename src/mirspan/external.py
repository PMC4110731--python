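"""Adapter to an external thermodynamic library (ViennaRNA) for parity
studies.

The bundled dynamic programs use a reduced parameter set; this engine
delegates the same two quantities to ViennaRNA's full Turner model:
``duplexfold`` for the hybridization MFE (intramolecular pairing
forbidden, as in the bundled model) and constrained ``fold_compound``
MFEs for the opening energy.  Absolute energies differ between engines by
design; both satisfy the model-level contracts (duplex MFE <= 0,
dG_open >= 0).
"""

from __future__ import annotations

from .energetics import SiteEnergies, SiteWindow

__all__ = ["ViennaEngine"]


class ViennaEngine:
    """Energy engine backed by the ViennaRNA python bindings."""

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "the external engine requires the ViennaRNA python bindings "
                "(package 'RNA')"
            ) from exc
        self._rna = RNA

    def duplex_energy(self, mirna_seq: str, window: SiteWindow) -> float:
        duplex = self._rna.duplexfold(mirna_seq, window.sequence)
        return min(0.0, float(duplex.energy))

    def opening_energy(self, window: SiteWindow) -> float:
        RNA = self._rna
        fc = RNA.fold_compound(window.sequence)
        _, mfe_free = fc.mfe()
        fc_c = RNA.fold_compound(window.sequence)
        for pos in range(window.site_start, window.site_end):
            fc_c.hc_add_up(pos + 1)  # ViennaRNA positions are 1-based
        _, mfe_blocked = fc_c.mfe()
        return max(0.0, float(mfe_blocked) - float(mfe_free))

    def site_energies(self, mirna_seq: str, window: SiteWindow) -> SiteEnergies:
        return SiteEnergies(
            dG_duplex=self.duplex_energy(mirna_seq, window),
            dG_open=self.opening_energy(window),
        )
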