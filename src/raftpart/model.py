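"""The raft-partitioning free-energy model.

A single-pass protein distributes between the liquid-ordered (raft) and
liquid-disordered phase of a membrane with partition coefficient K_p; the
apparent free energy is dG = −RT ln K_p, so negative dG means
raft-preferring. The model decomposes the predicted dG into three additive,
independent terms:

* an interfacial-tension (surface-area) penalty, Δγ · ASA — a TMD with more
  side-chain surface pays more to be solvated by the tightly packed raft
  phase;
* a palmitoylation gain, n_palm · dG_palm — each saturated acyl chain
  favors the cholesterol-rich phase;
* a hydrophobic-mismatch (mattress-model) term,
  −2·B_LP·(d_TMD − (d_Lo + d_Ld)/2) — longer TMDs prefer the thicker
  ordered phase.

The single-term area model (``predict_eq1``) keeps only the first term plus
a fitted constant offset dG_ex; it is the form whose slope against measured
data estimates Δγ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from . import physchem
from .palmitoylation import PalmConfig, PalmPredictor, count_palm_sites
from .physchem import CONSTANTS, R_KCAL_PER_MOL_K, ResidueScale, load_asa_scale
from .seqio import TMDRecord


@dataclass(frozen=True)
class ModelParams:
    """All physical constants of the tripartite model.

    delta_gamma: Δγ_TMD,Lo-Ld in pN/nm.
    dG_palm: kcal/mol per palmitoylated Cys (negative = raft-favoring).
    B_LP: mattress-model mismatch parameter, kcal/(mol·nm).
    d_lo, d_ld: hydrophobic thicknesses of the ordered/disordered phase, nm.
    temperature: K, used for K_p ↔ dG conversion.
    dG_ex: constant offset of the single-term area model only, kcal/mol.
    """

    delta_gamma: float
    dG_palm: float
    B_LP: float
    d_lo: float
    d_ld: float
    temperature: float = 283.15
    dG_ex: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_gamma", "dG_palm", "B_LP", "d_lo", "d_ld", "temperature", "dG_ex"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"ModelParams.{name} must be finite")
        if not (self.d_lo > self.d_ld > 0):
            raise ValueError(
                f"phase thicknesses must satisfy d_lo > d_ld > 0, "
                f"got d_lo={self.d_lo}, d_ld={self.d_ld}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def midplane_thickness(self) -> float:
        """(d_Lo + d_Ld)/2 in nm: the TMD length with zero mismatch energy."""
        return 0.5 * (self.d_lo + self.d_ld)


@dataclass(frozen=True)
class RaftPrediction:
    """Per-record decomposition of the predicted partitioning free energy."""

    record_id: str
    asa: float  # Å²
    asa_term: float  # kcal/mol
    n_palm: int
    palm_term: float  # kcal/mol
    d_tmd: float  # nm
    mismatch_term: float  # kcal/mol
    dG_pred: float  # kcal/mol
    kp_pred: float  # dimensionless

    def __post_init__(self) -> None:
        total = self.asa_term + self.palm_term + self.mismatch_term
        if abs(self.dG_pred - total) > 1e-9:
            raise ValueError(
                f"{self.record_id}: dG_pred {self.dG_pred} does not equal the "
                f"sum of its terms {total}"
            )


def load_params(path: str | Path) -> ModelParams:
    """Read a flat key=value parameter file ('#' comments allowed)."""
    path = Path(path)
    fields: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        fields[key] = float(raw)
    known = set(ModelParams.__dataclass_fields__)
    unknown = set(fields) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return ModelParams(**fields)


def default_params() -> ModelParams:
    """The shipped default parameter set.

    Emits a warning: the mismatch parameters (B_LP, d_lo, d_ld) are
    documented placeholders, not published calibrated values.
    """
    params = load_params(physchem._data_path("default_params.cfg"))
    warnings.warn(
        "default ModelParams carry placeholder mismatch parameters "
        "(B_LP, d_lo, d_ld); supply calibrated values for quantitative work",
        UserWarning,
        stacklevel=2,
    )
    return params


def dG_from_kp(kp: float, temperature: float) -> float:
    """dG = −RT ln K_p in kcal/mol; negative iff kp > 1."""
    if not (kp > 0):
        raise ValueError(f"K_p must be > 0, got {kp!r}")
    return -R_KCAL_PER_MOL_K * temperature * math.log(kp)


def kp_from_dG(dG: float, temperature: float) -> float:
    """Inverse of :func:`dG_from_kp`: K_p = exp(−dG / RT)."""
    return math.exp(-dG / (R_KCAL_PER_MOL_K * temperature))


def mismatch_energy(d_tmd: float, params: ModelParams) -> float:
    """Mattress-model mismatch term: −2·B_LP·(d_TMD − (d_Lo+d_Ld)/2).

    Zero at the midpoint thickness; for B_LP > 0, longer TMDs get a more
    negative (raft-favoring) value.
    """
    return -2.0 * params.B_LP * (d_tmd - params.midplane_thickness)


def gamma_kcal_per_mol_A2(params: ModelParams) -> float:
    """Δγ converted from pN/nm into the slope units of dG versus ASA."""
    return physchem.convert_tension(params.delta_gamma, "pN_per_nm", "kcal_per_mol_A2")


def predict_eq1(asa: float, params: ModelParams) -> float:
    """Single-term area model: dG = Δγ(converted)·ASA + dG_ex, kcal/mol."""
    if asa < 0:
        raise ValueError(f"ASA must be >= 0, got {asa!r}")
    return gamma_kcal_per_mol_A2(params) * asa + params.dG_ex


def predict(
    record: TMDRecord,
    params: ModelParams,
    scale: ResidueScale | None = None,
    palm_config: PalmConfig = PalmConfig(),
    palm_predictor: PalmPredictor | None = None,
) -> RaftPrediction:
    """Tripartite prediction with full term-by-term decomposition.

    ``palm_predictor`` may replace the default Cys-counting rule; the
    record's ``n_palm_override`` always wins over either.
    """
    scale = scale or load_asa_scale()
    try:
        asa = physchem.tmd_asa(record, scale)
        if record.n_palm_override is not None:
            n_palm = int(record.n_palm_override)
        elif palm_predictor is not None:
            n_palm = int(palm_predictor(record))
        else:
            n_palm = count_palm_sites(record, palm_config)
        d_tmd = physchem.tmd_length_nm(record, CONSTANTS)
    except Exception as exc:
        raise type(exc)(f"record {record.id!r}: {exc}") from exc
    asa_term = gamma_kcal_per_mol_A2(params) * asa
    palm_term = n_palm * params.dG_palm
    mm_term = mismatch_energy(d_tmd, params)
    dG = asa_term + palm_term + mm_term
    return RaftPrediction(
        record_id=record.id,
        asa=asa,
        asa_term=asa_term,
        n_palm=n_palm,
        palm_term=palm_term,
        d_tmd=d_tmd,
        mismatch_term=mm_term,
        dG_pred=dG,
        kp_pred=kp_from_dG(dG, params.temperature),
    )
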