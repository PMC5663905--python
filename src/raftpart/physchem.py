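"""Residue-level physical scales and unit-bearing conversions.

This module owns every quantity with units: summation of side-chain
accessible surface area (ASA, Å²) over a transmembrane span, Kyte-Doolittle
hydropathy, conversion of residue counts to helix length (nm), and the
algebraic conversions between the three interfacial-tension unit systems
used in membrane biophysics (pN/nm, kT/nm², kcal/(mol·Å²)).

Scales are plain per-residue lookup tables (:class:`ResidueScale`) loaded
from two-column TSV files shipped with the package, so an alternative ASA
table can be swapped in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import TMDRecord

#: The 20 standard amino-acid one-letter codes. Ambiguity codes (B, Z, X,
#: U, O) are rejected throughout: no physical scale has a defensible value
#: for them.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

TENSION_UNITS = ("pN_per_nm", "kT_per_nm2", "kcal_per_mol_A2")


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants plus the helix geometry used for d_TMD.

    ``helix_rise_A`` is the per-residue rise of a canonical α-helix
    (1.5 Å/residue); it converts a TMD residue count into a physical
    length.
    """

    boltzmann_k: float = 1.380649e-23  # J/K
    avogadro: float = 6.02214076e23  # 1/mol
    joules_per_kcal: float = 4184.0
    helix_rise_A: float = 1.5  # Å per residue

    @property
    def gas_constant_R(self) -> float:
        """R in kcal/(mol·K), derived exactly from k_B and N_A."""
        return self.boltzmann_k * self.avogadro / self.joules_per_kcal

    def __post_init__(self) -> None:
        for name in ("boltzmann_k", "avogadro", "joules_per_kcal", "helix_rise_A"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"PhysicalConstants.{name} must be finite and > 0, got {v!r}")


CONSTANTS = PhysicalConstants()

#: Gas constant in kcal/(mol·K) — 1.98720425864083e-3.
R_KCAL_PER_MOL_K = CONSTANTS.gas_constant_R


@dataclass(frozen=True)
class ResidueScale:
    """A per-residue lookup table covering the 20 standard amino acids."""

    name: str
    values: Mapping[str, float]
    units: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != AMINO_ACIDS:
            missing = sorted(AMINO_ACIDS - keys)
            extra = sorted(keys - AMINO_ACIDS)
            raise ValueError(
                f"ResidueScale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing: {missing}, unexpected: {extra})"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"ResidueScale {self.name!r}: non-finite value for {aa}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None, units: str = "") -> "ResidueScale":
        """Load a scale from a two-column TSV ('#' lines are comments)."""
        path = Path(path)
        values: dict[str, float] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'residue<TAB>value', got {line!r}")
            aa, raw = parts
            values[aa.strip().upper()] = float(raw)
        return cls(name=name or path.stem, values=values, units=units)


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("raftpart.data") / filename))


def load_asa_scale() -> ResidueScale:
    """The shipped side-chain ASA scale (Å² per residue, Gly-X-Gly context)."""
    scale = ResidueScale.from_tsv(_data_path("asa_sidechain.tsv"), units="A^2")
    # side chains have positive area except Gly, which has none
    for aa, v in scale.values.items():
        if v < 0 or (v == 0 and aa != "G"):
            raise ValueError(f"ASA scale value for {aa} must be positive (Gly may be 0)")
    return scale


def load_kd_scale() -> ResidueScale:
    """The shipped Kyte-Doolittle hydropathy scale (dimensionless)."""
    return ResidueScale.from_tsv(_data_path("kyte_doolittle.tsv"), units="dimensionless")


def _scan_span(record: "TMDRecord", scale: ResidueScale) -> list[float]:
    out = []
    for pos in range(record.tmd_start, record.tmd_end + 1):
        aa = record.sequence[pos - 1]
        if aa not in scale.values:
            raise KeyError(
                f"record {record.id!r}: residue {aa!r} at position {pos} "
                f"is not covered by scale {scale.name!r}"
            )
        out.append(scale.values[aa])
    return out


def tmd_asa(record: "TMDRecord", scale: ResidueScale) -> float:
    """Aggregate side-chain ASA (Å²) over the annotated TMD span.

    Strictly additive: the sum of per-residue values between
    ``tmd_start`` and ``tmd_end`` inclusive; order-independent by
    construction.
    """
    return float(sum(_scan_span(record, scale)))


def tmd_hydrophobicity(record: "TMDRecord", scale: ResidueScale) -> tuple[float, float]:
    """Summed and mean Kyte-Doolittle hydropathy over the TMD span."""
    vals = _scan_span(record, scale)
    total = float(sum(vals))
    return total, total / len(vals)


def tmd_length_nm(record: "TMDRecord", constants: PhysicalConstants = CONSTANTS) -> float:
    """Physical TMD length d_TMD in nm: residue count × helix rise."""
    n_res = record.tmd_end - record.tmd_start + 1
    return n_res * constants.helix_rise_A / 10.0


def _to_joules_per_m2(unit: str, temperature: float | None, c: PhysicalConstants) -> float:
    """Conversion factor from `unit` to J/m² (= N/m)."""
    if unit == "pN_per_nm":
        # 1 pN/nm = 1e-12 N / 1e-9 m = 1e-3 N/m
        return 1e-3
    if unit == "kT_per_nm2":
        if temperature is None:
            raise ValueError("temperature is required for kT-based units")
        # 1 kT/nm² = k_B·T J / 1e-18 m²
        return c.boltzmann_k * temperature * 1e18
    if unit == "kcal_per_mol_A2":
        # 1 kcal/(mol·Å²) = (4184 / N_A) J per 1e-20 m²
        return c.joules_per_kcal / c.avogadro * 1e20
    raise ValueError(f"unknown tension unit {unit!r}; expected one of {TENSION_UNITS}")


def convert_tension(
    value: float,
    from_unit: str,
    to_unit: str,
    temperature: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Convert an interfacial tension between unit systems.

    ``temperature`` (K) is required whenever a kT-based unit is involved —
    kT/nm² is temperature-dependent and a silent default would hide a
    physical choice. The conversion is exactly invertible.
    """
    if not math.isfinite(value):
        raise ValueError(f"tension value must be finite, got {value!r}")
    if temperature is not None and temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature!r}")
    if from_unit == to_unit:
        # still validate the unit name
        _to_joules_per_m2(from_unit, temperature if "kT" in from_unit else 1.0, constants)
        return value
    si = value * _to_joules_per_m2(from_unit, temperature, constants)
    return si / _to_joules_per_m2(to_unit, temperature, constants)


#: kcal/(mol·Å²) per (pN/nm): the factor that converts Δγ as fitted in
#: mechanical units into the slope of ΔG versus ASA (≈ 1.4394e-3).
KCAL_PER_MOL_A2_PER_PN_NM = convert_tension(1.0, "pN_per_nm", "kcal_per_mol_A2")
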