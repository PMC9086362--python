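"""Expected nanorod lengths from TMV virion geometry.

TMV packages its RNA at three nucleotides per coat-protein subunit, so rod
length is proportional to the length of the encapsidated RNA. The linear
scale is calibrated on the full virion: the 6,395-nt U1/Vulgare genome
builds a 300-nm particle, i.e. ~0.0469 nm per nucleotide. A ~1.0-kb
subgenomic RNA therefore yields the 49-nm rod class, and end-to-end
aggregation of that unit produces apparent 98- and 147-nm classes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TmvGeometry:
    """Reference constants of the TMV virion."""

    nt_per_subunit: int = 3
    reference_length_nm: float = 300.0
    reference_nt: int = 6395
    rod_width_nm: float = 18.0

    def __post_init__(self) -> None:
        if min(self.nt_per_subunit, self.reference_nt) <= 0:
            raise ValueError("nucleotide counts must be positive")
        if min(self.reference_length_nm, self.rod_width_nm) <= 0:
            raise ValueError("lengths must be positive")

    @property
    def nm_per_nt(self) -> float:
        """Axial rise per encapsidated nucleotide (~0.04691 nm)."""
        return self.reference_length_nm / self.reference_nt


def expected_length(n_nt: int, geom: TmvGeometry | None = None) -> float:
    """Expected rod length (nm) for an RNA of ``n_nt`` nucleotides."""
    if geom is None:
        geom = TmvGeometry()
    if not n_nt > 0:
        raise ValueError(f"n_nt must be positive, got {n_nt}")
    return n_nt * geom.nm_per_nt


def multimer_length(k: int, unit_length_nm: float) -> float:
    """Length (nm) of an end-to-end aggregate of ``k`` unit rods."""
    if k < 1:
        raise ValueError(f"multimer order k must be >= 1, got {k}")
    if not unit_length_nm > 0:
        raise ValueError("unit_length_nm must be positive")
    return k * unit_length_nm
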