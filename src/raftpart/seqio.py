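"""Sequence and annotation I/O: FASTA, annotation TSV, TMD records.

The central container is :class:`TMDRecord`: one single-pass membrane
protein (or engineered construct) with its full sequence, the 1-based
inclusive span of the transmembrane domain (TMD), and the topological
orientation of that span. ``exo_to_cyto`` means the N-terminal end of the
TMD faces the exoplasm/lumen and the C-terminal end faces the cytoplasm
(type-II-like constructs such as trLAT); ``cyto_to_exo`` is the reverse.

A hydropathy-window fallback TMD caller is provided for sequences that
arrive without annotation. It is a deliberately simple stand-in for a
dedicated topology predictor and should be treated as a rough guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .physchem import AMINO_ACIDS, ResidueScale, load_kd_scale, _data_path

logger = logging.getLogger(__name__)

ORIENTATIONS = ("exo_to_cyto", "cyto_to_exo")
COMPARTMENTS = ("PM", "ER", "Golgi", "other")

#: The wild-type trLAT construct sequence (TMD of the Linker for Activation
#: of T cells plus short flanks). The only construct shipped verbatim; all
#: variants are generated programmatically (see :mod:`raftpart.synthetic`).
TRLAT_SEQUENCE = "MEEAILVPCVLGLLLLPILAMLMALCVHCHRLPGS"


class FastaParseError(ValueError):
    pass


class FastaRecord(NamedTuple):
    id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class TMDRecord:
    """One protein/construct with an annotated TMD span.

    Coordinates are 1-based and inclusive, matching biological annotation
    convention. ``n_palm_override`` short-circuits the palmitoylation
    counting rule (e.g. when experimentally determined stoichiometry is
    known). Set ``validate=False`` only when deliberately carrying an
    unvalidated row through a batch pipeline that handles rejects.
    """

    id: str
    sequence: str
    tmd_start: int
    tmd_end: int
    orientation: str = "exo_to_cyto"
    compartment: str | None = None
    n_palm_override: int | None = None
    description: str = ""
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.validate:
            return
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"record {self.id!r}: sequence contains non-standard letters "
                f"{sorted(bad)} (ambiguity codes are rejected, not scored)"
            )
        if not (1 <= self.tmd_start <= self.tmd_end <= len(self.sequence)):
            raise ValueError(
                f"record {self.id!r}: invalid TMD span {self.tmd_start}..{self.tmd_end} "
                f"for sequence of length {len(self.sequence)}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"record {self.id!r}: orientation {self.orientation!r} "
                f"not in {ORIENTATIONS}"
            )
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"record {self.id!r}: compartment {self.compartment!r} not in {COMPARTMENTS}"
            )
        if self.n_palm_override is not None and self.n_palm_override < 0:
            raise ValueError(f"record {self.id!r}: n_palm_override must be >= 0")

    @property
    def tmd_seq(self) -> str:
        return self.sequence[self.tmd_start - 1 : self.tmd_end]

    @property
    def tmd_len(self) -> int:
        return self.tmd_end - self.tmd_start + 1

    @property
    def cyto_terminus(self) -> int:
        """Position (1-based) of the TMD residue facing the cytoplasm."""
        return self.tmd_end if self.orientation == "exo_to_cyto" else self.tmd_start


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file; whitespace stripped, sequences uppercased.

    The text after the first whitespace of a header is retained as
    ``description``, separate from ``id``. An empty file yields an empty
    list (with a warning); sequence data before the first header is a
    parse error naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}:{lineno}: sequence data before first FASTA header: {line.strip()!r}"
            )
        break
    records = [
        FastaRecord(
            id=rec.id,
            sequence="".join(str(rec.seq).split()).upper(),
            description=rec.description[len(rec.id) :].strip(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[FastaRecord | tuple], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at `width` columns."""
    seqrecords = []
    for rec in records:
        rec = FastaRecord(*rec)
        seqrecords.append(
            SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        )
    with open(path, "w") as fh:
        SeqIO.FastaIO.FastaWriter(fh, wrap=width).write_file(seqrecords)


_ANNOT_REQUIRED = ["id", "tmd_start", "tmd_end", "orientation"]
_ANNOT_OPTIONAL = ["compartment", "n_palm"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-protein annotation TSV.

    Required columns: id, tmd_start, tmd_end, orientation. Optional:
    compartment, n_palm. '#' lines are comments; unknown columns are
    preserved but ignored downstream. Orientation defaults to
    ``exo_to_cyto`` where empty.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _ANNOT_REQUIRED if c not in df.columns and c != "orientation"]
    if missing:
        raise ValueError(f"{path}: missing required annotation columns {missing}")
    if df.empty:
        return pd.DataFrame(columns=_ANNOT_REQUIRED + _ANNOT_OPTIONAL)

    dups = df["id"][df["id"].duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicate annotation ids: {dups}")

    for col in ("tmd_start", "tmd_end"):
        for i, raw in df[col].items():
            try:
                int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer {col}={raw!r} in row for id {df['id'][i]!r}"
                ) from None
        df[col] = df[col].astype(int)

    bad_span = df[df["tmd_end"] < df["tmd_start"]]
    if not bad_span.empty:
        raise ValueError(
            f"{path}: tmd_end < tmd_start for ids {bad_span['id'].tolist()}"
        )

    if "orientation" not in df.columns:
        df["orientation"] = "exo_to_cyto"
    df["orientation"] = df["orientation"].fillna("exo_to_cyto")
    bad_orient = sorted(set(df["orientation"]) - set(ORIENTATIONS))
    if bad_orient:
        raise ValueError(f"{path}: unknown orientation value(s) {bad_orient}")

    if "compartment" not in df.columns:
        df["compartment"] = None
    df["compartment"] = df["compartment"].where(pd.notna(df["compartment"]), None)
    if "n_palm" not in df.columns:
        df["n_palm"] = None
    df["n_palm"] = [None if pd.isna(v) else int(v) for v in df["n_palm"]]
    return df


def build_records(
    sequences: Sequence[FastaRecord | tuple],
    annotations: pd.DataFrame,
) -> list[TMDRecord]:
    """Join sequences with annotation rows into validated TMDRecords.

    Every annotation id must have a sequence; sequences lacking an
    annotation are skipped with a log message. Row order of the annotation
    table does not affect the resulting record set.
    """
    seq_by_id: dict[str, FastaRecord] = {}
    for rec in sequences:
        rec = FastaRecord(*rec)
        seq_by_id[rec.id] = rec
    records = []
    for _, row in annotations.iterrows():
        rid = row["id"]
        if rid not in seq_by_id:
            raise ValueError(f"annotation id {rid!r} has no matching sequence")
        records.append(
            TMDRecord(
                id=rid,
                sequence=seq_by_id[rid].sequence,
                tmd_start=int(row["tmd_start"]),
                tmd_end=int(row["tmd_end"]),
                orientation=row["orientation"],
                compartment=row.get("compartment"),
                n_palm_override=row.get("n_palm"),
                description=seq_by_id[rid].description,
            )
        )
    annotated = {r.id for r in records}
    for sid in seq_by_id:
        if sid not in annotated:
            logger.info("sequence %r has no annotation; skipped", sid)
    return records


def fallback_tmd_caller(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    scale: ResidueScale | None = None,
) -> tuple[int, int] | None:
    """Crude hydropathy-window TMD caller (annotation fallback only).

    Slides a Kyte-Doolittle mean-hydropathy window over the sequence and
    returns, as a (start, end) 1-based span, the longest contiguous run of
    window-center positions whose windowed mean exceeds ``threshold``.
    Ties break to the most N-terminal run. Returns None when no center
    qualifies, or (with a warning) when the sequence is shorter than the
    window.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    if len(sequence) < window:
        logger.warning("sequence of length %d shorter than window %d", len(sequence), window)
        return None
    scale = scale or load_kd_scale()
    vals = [scale[aa] for aa in sequence]
    half = window // 2
    centers = []  # 1-based positions whose windowed mean exceeds threshold
    for center in range(half + 1, len(sequence) - half + 1):
        mean = sum(vals[center - 1 - half : center + half]) / window
        if mean > threshold:
            centers.append(center)
    if not centers:
        return None
    # longest contiguous run, earliest on ties
    best_start = best_len = 0
    run_start, run_len = centers[0], 1
    for prev, cur in zip(centers, centers[1:]):
        if cur == prev + 1:
            run_len += 1
        else:
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start, run_len = cur, 1
    if run_len > best_len:
        best_start, best_len = run_start, run_len
    return best_start, best_start + best_len - 1


def trlat_record() -> TMDRecord:
    """The shipped wild-type trLAT fixture (sequence + span convention)."""
    seqs = read_fasta(_data_path("trlat.fasta"))
    annots = read_annotations(_data_path("trlat_annotations.tsv"))
    return build_records(seqs, annots)[0]
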