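"""Generators for synthetic constructs and simulated measurements.

Every generator is a pure function of its arguments and seed, and emits
validated :class:`~raftpart.seqio.TMDRecord` objects, so the whole pipeline
can be exercised offline with known ground truth.

Synthetic TMDs are embedded in the juxtamembrane context of the trLAT
construct — the N-terminal flank ``MEEA`` and the cytoplasmic flank
``HCHRLPGS`` (which carries a palmitoylatable Cys two residues past the
TMD). A Cys-free cytoplasmic flank variant is available for populations
meant to be unpalmitoylated.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, predict
from .palmitoylation import PalmConfig
from .physchem import ResidueScale
from .seqio import FastaRecord, TMDRecord, write_fasta

N_FLANK = "MEEA"
C_FLANK_PALM = "HCHRLPGS"  # trLAT cytoplasmic flank: one juxtamembrane Cys
C_FLANK_NOPALM = "HSHRLPGS"  # same flank with the Cys substituted away


def _embed(tmd: str, rid: str, compartment: str | None = None, palm_flank: bool = True) -> TMDRecord:
    c_flank = C_FLANK_PALM if palm_flank else C_FLANK_NOPALM
    return TMDRecord(
        id=rid,
        sequence=N_FLANK + tmd + c_flank,
        tmd_start=len(N_FLANK) + 1,
        tmd_end=len(N_FLANK) + len(tmd),
        orientation="exo_to_cyto",
        compartment=compartment,
    )


def make_ala_leu_series(
    length: int,
    leu_counts: Sequence[int],
    seed: int,
    palm_flank: bool = True,
) -> list[TMDRecord]:
    """Compositional Ala/Leu TMD series of fixed length and varying ASA.

    For each requested Leu count, a TMD of ``length`` residues with that
    many Leu at seeded-random positions (remainder Ala) is embedded in the
    trLAT flanking scaffold. ASA increases strictly with the Leu count.
    """
    rng = np.random.default_rng(seed)
    records = []
    for count in leu_counts:
        if not 0 <= count <= length:
            raise ValueError(f"leu_count {count} out of range 0..{length}")
        tmd = ["A"] * length
        for pos in rng.choice(length, size=count, replace=False):
            tmd[pos] = "L"
        records.append(_embed("".join(tmd), f"AL{length}_L{count:02d}", palm_flank=palm_flank))
    return records


def scramble_core(record: TMDRecord, core_span: tuple[int, int], seed: int) -> TMDRecord:
    """Permute the residues within ``core_span`` (1-based, inside the TMD).

    The residue multiset — and hence every compositional quantity such as
    ASA — is preserved exactly.
    """
    lo, hi = core_span
    if not (record.tmd_start <= lo <= hi <= record.tmd_end):
        raise ValueError(
            f"core span {lo}..{hi} must lie within the TMD "
            f"{record.tmd_start}..{record.tmd_end}"
        )
    rng = np.random.default_rng(seed)
    seq = list(record.sequence)
    core = seq[lo - 1 : hi]
    perm = rng.permutation(len(core))
    seq[lo - 1 : hi] = [core[i] for i in perm]
    return replace(record, id=record.id + "_scr", sequence="".join(seq))


def truncate_tmd(record: TMDRecord, n_removed: int, end: str) -> TMDRecord:
    """Delete ``n_removed`` residues from one end of the TMD.

    ``end`` is ``"exoplasmic"`` or ``"cytoplasmic"`` and is resolved
    against the record's orientation. Sequence outside the TMD is
    unchanged; the span is updated. Cytoplasmic truncation can remove
    counted palmitoylation cysteines; exoplasmic truncation cannot.
    """
    if end not in ("exoplasmic", "cytoplasmic"):
        raise ValueError(f"end must be 'exoplasmic' or 'cytoplasmic', got {end!r}")
    if not 0 < n_removed < record.tmd_len:
        raise ValueError(
            f"n_removed must be in 1..{record.tmd_len - 1}, got {n_removed}"
        )
    # which sequence side of the span is being cut
    if record.orientation == "exo_to_cyto":
        cut_nterm = end == "exoplasmic"
    else:
        cut_nterm = end == "cytoplasmic"
    s, e = record.tmd_start, record.tmd_end
    seq = record.sequence
    if cut_nterm:
        new_seq = seq[: s - 1] + seq[s - 1 + n_removed :]
    else:
        new_seq = seq[: e - n_removed] + seq[e:]
    return replace(
        record,
        id=f"{record.id}_d{n_removed}{end[:4]}",
        sequence=new_seq,
        tmd_end=e - n_removed,
    )


#: Compartment-typical TMD design profiles for synthetic populations:
#: plasma-membrane-like TMDs are longer, Ala-rich (small ASA) and carry the
#: palmitoylatable flank; ER/Golgi-like TMDs are shorter, Leu-rich and
#: unpalmitoylated — the feature directions observed proteome-wide.
COMPARTMENT_PROFILES: dict[str, dict] = {
    "PM": dict(length_mean=24.0, length_sd=1.5, leu_frac=0.25, palm_flank=True),
    "ER": dict(length_mean=20.0, length_sd=1.5, leu_frac=0.70, palm_flank=False),
    "Golgi": dict(length_mean=20.5, length_sd=1.5, leu_frac=0.65, palm_flank=False),
}


def make_compartment_set(
    n: int,
    compartment: str,
    seed: int,
    length_mean: float | None = None,
    length_sd: float | None = None,
    leu_frac: float | None = None,
    palm_flank: bool | None = None,
) -> list[TMDRecord]:
    """A population of Ala/Leu TMD records with compartment-typical features.

    Lengths are drawn from a rounded normal (clipped to >= 12 residues) and
    Leu counts from a binomial with the profile's Leu fraction. Explicit
    keyword arguments override the profile for ``compartment``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    profile = dict(COMPARTMENT_PROFILES.get(compartment, COMPARTMENT_PROFILES["ER"]))
    for key, val in (
        ("length_mean", length_mean),
        ("length_sd", length_sd),
        ("leu_frac", leu_frac),
        ("palm_flank", palm_flank),
    ):
        if val is not None:
            profile[key] = val
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(np.clip(round(rng.normal(profile["length_mean"], profile["length_sd"])), 12, 40))
        count = int(rng.binomial(length, profile["leu_frac"]))
        tmd = ["A"] * length
        for pos in rng.choice(length, size=count, replace=False):
            tmd[pos] = "L"
        rec = _embed(
            "".join(tmd),
            f"{compartment}_{i:04d}",
            compartment=compartment,
            palm_flank=profile["palm_flank"],
        )
        records.append(rec)
    return records


def simulate_dG_app(
    records: Sequence[TMDRecord],
    params: ModelParams,
    scale: ResidueScale | None = None,
    palm_config: PalmConfig = PalmConfig(),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated apparent free energies: model prediction + Gaussian noise.

    ``noise_sd`` (kcal/mol) emulates measurement scatter between vesicle
    preparations; zero noise reproduces the predictions exactly. Returns a
    DataFrame with columns ``id``, ``asa``, ``dG_app``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        pred = predict(rec, params, scale=scale, palm_config=palm_config)
        rows.append(
            dict(id=rec.id, asa=pred.asa, dG_app=pred.dG_pred + rng.normal(0.0, noise_sd))
        )
    return pd.DataFrame(rows)


def write_series(
    records: Sequence[TMDRecord],
    fasta_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Emit records as FASTA + annotation TSV re-ingestible by the pipeline."""
    write_fasta(
        [FastaRecord(r.id, r.sequence, r.description) for r in records], fasta_path
    )
    rows = []
    for r in records:
        rows.append(
            dict(
                id=r.id,
                tmd_start=r.tmd_start,
                tmd_end=r.tmd_end,
                orientation=r.orientation,
                compartment="" if r.compartment is None else r.compartment,
                n_palm="" if r.n_palm_override is None else r.n_palm_override,
            )
        )
    pd.DataFrame(rows).to_csv(annotations_path, sep="\t", index=False)
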