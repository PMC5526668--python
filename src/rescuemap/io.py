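"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions (the single source of truth):

* internal: 0-based, half-open ``[start, end)``;
* GFF3: 1-based, closed ``start..end``;
* BED: 0-based, half-open (identical to internal, no shift).

Plate data are tidy (long) CSV with columns
``plate_id, well, day, od600, yfp, cfp``; a wide-to-long converter is
available for plate-shaped sheets (one row per well, one column per day).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PlateFormatError",
    "AnnotationError",
    "PlateSeries",
    "Gene",
    "Promoter",
    "Terminator",
    "AnnotationBundle",
    "QpcrRecord",
    "read_plate_csv",
    "write_plate_csv",
    "wide_to_long",
    "read_annotation",
    "write_annotation_gff3",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_qpcr_csv",
    "qpcr_records_from_table",
    "write_qpcr_csv",
]


class PlateFormatError(ValueError):
    """Malformed plate-reader CSV (reported with offending row numbers)."""


class AnnotationError(ValueError):
    """Malformed or out-of-bounds genome annotation."""


# ---------------------------------------------------------------------------
# plate-reader time series
# ---------------------------------------------------------------------------


@dataclass
class PlateSeries:
    """Daily OD600/YFP/CFP readings for one well; the unit of trajectory analysis.

    Days are 1-based and contiguous (day ``T`` is the final measurement).
    Fluorescence is in the reader's relative fluorescence units (RFU).
    """

    plate_id: str
    well: str
    days: np.ndarray
    od600: np.ndarray
    yfp: np.ndarray
    cfp: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.cfp = np.asarray(self.cfp, dtype=float)
        n = len(self.days)
        if not (len(self.od600) == len(self.yfp) == len(self.cfp) == n):
            raise PlateFormatError(
                f"{self.plate_id}/{self.well}: ragged channel lengths"
            )
        if n == 0:
            raise PlateFormatError(f"{self.plate_id}/{self.well}: empty series")
        if not np.array_equal(self.days, np.arange(1, n + 1)):
            raise PlateFormatError(
                f"{self.plate_id}/{self.well}: days must be contiguous 1..T, "
                f"got {self.days.tolist()}"
            )
        for name, arr in (("od600", self.od600), ("yfp", self.yfp), ("cfp", self.cfp)):
            if not np.all(np.isfinite(arr)):
                raise PlateFormatError(
                    f"{self.plate_id}/{self.well}: non-finite {name} value"
                )
            if np.any(arr < 0):
                raise PlateFormatError(
                    f"{self.plate_id}/{self.well}: negative {name} value"
                )

    @property
    def n_days(self) -> int:
        return len(self.days)


_PLATE_COLUMNS = ["plate_id", "well", "day", "od600", "yfp", "cfp"]


def read_plate_csv(path: str | Path, *, strict: bool = True) -> list[PlateSeries]:
    """Read a tidy plate CSV into validated :class:`PlateSeries`.

    Errors (missing column, duplicate ``(plate, well, day)``, negative or
    non-finite value, ragged day range) are raised as
    :class:`PlateFormatError` with the offending CSV row number(s).
    With ``strict=False`` missing fluorescence values (NA) are forward-filled
    per well instead of rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing column(s): {', '.join(missing)}")
    # +2: header line plus 1-based numbering
    df = df.assign(_row=df.index + 2)

    dup = df.duplicated(subset=["plate_id", "well", "day"], keep=False)
    if dup.any():
        rows = df.loc[dup, "_row"].tolist()
        raise PlateFormatError(f"duplicate (plate_id, well, day) at rows {rows}")

    na_mask = df[["od600", "yfp", "cfp"]].isna().any(axis=1)
    if na_mask.any():
        if strict:
            rows = df.loc[na_mask, "_row"].tolist()
            raise PlateFormatError(f"missing values at rows {rows} (strict mode)")
        df = df.sort_values(["plate_id", "well", "day"])
        df[["od600", "yfp", "cfp"]] = (
            df.groupby(["plate_id", "well"])[["od600", "yfp", "cfp"]].ffill()
        )
        if df[["od600", "yfp", "cfp"]].isna().any(axis=None):
            raise PlateFormatError("NA on the first day of a well cannot be imputed")

    bad = df[(df[["od600", "yfp", "cfp"]] < 0).any(axis=1)]
    if len(bad):
        raise PlateFormatError(f"negative value(s) at rows {bad['_row'].tolist()}")

    out: list[PlateSeries] = []
    for (plate, well), grp in df.groupby(["plate_id", "well"], sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise PlateFormatError(
                f"{plate}/{well}: ragged day range {days.tolist()} "
                f"(rows {grp['_row'].tolist()})"
            )
        out.append(
            PlateSeries(
                plate_id=str(plate),
                well=str(well),
                days=days,
                od600=grp["od600"].to_numpy(float),
                yfp=grp["yfp"].to_numpy(float),
                cfp=grp["cfp"].to_numpy(float),
            )
        )
    lengths = {s.n_days for s in out}
    if len(lengths) > 1:
        raise PlateFormatError(f"wells with differing day ranges: T in {sorted(lengths)}")
    return out


def write_plate_csv(series: Iterable[PlateSeries], path: str | Path) -> None:
    """Write tidy plate CSV (inverse of :func:`read_plate_csv`)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PLATE_COLUMNS)
        for s in series:
            for i in range(s.n_days):
                w.writerow(
                    [
                        s.plate_id,
                        s.well,
                        int(s.days[i]),
                        repr(float(s.od600[i])),
                        repr(float(s.yfp[i])),
                        repr(float(s.cfp[i])),
                    ]
                )


def wide_to_long(
    wide: pd.DataFrame,
    channel: str,
    *,
    plate_id: str = "plate1",
    well_column: str = "well",
) -> pd.DataFrame:
    """Convert a plate-shaped sheet (one row per well, day columns) to tidy rows.

    Day columns may be named ``1..T`` or ``day1..dayT``. Returns a frame with
    columns ``plate_id, well, day, <channel>`` ready to be merged with the
    other channels.
    """
    day_cols = {}
    for c in wide.columns:
        name = str(c)
        if name == well_column:
            continue
        stripped = name[3:] if name.lower().startswith("day") else name
        if stripped.isdigit():
            day_cols[c] = int(stripped)
    if not day_cols:
        raise PlateFormatError("no day columns found in wide sheet")
    long = wide.melt(
        id_vars=[well_column], value_vars=list(day_cols), var_name="day", value_name=channel
    )
    long["day"] = long["day"].map(day_cols)
    long["plate_id"] = plate_id
    return long.rename(columns={well_column: "well"})[
        ["plate_id", "well", "day", channel]
    ].sort_values(["well", "day"], ignore_index=True)


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

_STRANDS = ("+", "-")
_TERMINATOR_MODES = ("intrinsic", "rho")


@dataclass(frozen=True)
class Gene:
    id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    essential: bool = False


@dataclass(frozen=True)
class Promoter:
    pos: int  # representative point, 0-based
    strand: str
    primary: bool = True


@dataclass(frozen=True)
class Terminator:
    pos: int  # representative point, 0-based
    strand: str
    mode: str = "intrinsic"  # 'intrinsic' | 'rho'


@dataclass
class AnnotationBundle:
    """Strand-aware genes, promoters and terminators on one (optionally
    circular) replicon, in internal 0-based half-open coordinates."""

    genome_length: int
    circular: bool = True
    genes: list[Gene] = field(default_factory=list)
    promoters: list[Promoter] = field(default_factory=list)
    terminators: list[Terminator] = field(default_factory=list)
    sequence: str | None = None
    seqid: str = "chrom"

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise AnnotationError("genome_length must be positive")
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise AnnotationError(
                f"sequence length {len(self.sequence)} != genome_length "
                f"{self.genome_length}"
            )
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.genome_length):
                raise AnnotationError(f"gene {g.id}: interval ({g.start}, {g.end}) out of bounds")
            if g.strand not in _STRANDS:
                raise AnnotationError(f"gene {g.id}: unknown strand {g.strand!r}")
        for p in self.promoters:
            if not (0 <= p.pos < self.genome_length):
                raise AnnotationError(f"promoter at {p.pos} out of bounds")
            if p.strand not in _STRANDS:
                raise AnnotationError(f"promoter at {p.pos}: unknown strand {p.strand!r}")
        for t in self.terminators:
            if not (0 <= t.pos < self.genome_length):
                raise AnnotationError(f"terminator at {t.pos} out of bounds")
            if t.strand not in _STRANDS:
                raise AnnotationError(f"terminator at {t.pos}: unknown strand {t.strand!r}")
            if t.mode not in _TERMINATOR_MODES:
                raise AnnotationError(f"terminator at {t.pos}: unknown mode {t.mode!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.id))
        self.promoters = sorted(self.promoters, key=lambda p: p.pos)
        self.terminators = sorted(self.terminators, key=lambda t: t.pos)

    def reverse_complement(self) -> "AnnotationBundle":
        """Mirror every feature onto the opposite strand (coordinate flip)."""
        L = self.genome_length
        seq = None
        if self.sequence is not None:
            seq = str(Seq(self.sequence).reverse_complement())
        flip = {"+": "-", "-": "+"}
        return AnnotationBundle(
            genome_length=L,
            circular=self.circular,
            genes=[
                Gene(g.id, L - g.end, L - g.start, flip[g.strand], g.essential)
                for g in self.genes
            ],
            promoters=[Promoter(L - 1 - p.pos, flip[p.strand], p.primary) for p in self.promoters],
            terminators=[
                Terminator(L - 1 - t.pos, flip[t.strand], t.mode) for t in self.terminators
            ],
            sequence=seq,
            seqid=self.seqid,
        )


def _parse_bool(token: str) -> bool:
    if token.lower() in ("true", "1", "yes"):
        return True
    if token.lower() in ("false", "0", "no"):
        return False
    raise AnnotationError(f"unknown boolean token {token!r}")


def _read_annotation_gff3(path: str | Path, circular: bool | None) -> AnnotationBundle:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome_length = None
    seqid = "chrom"
    is_circular = True if circular is None else circular
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            seqid = parts[1]
            genome_length = int(parts[3])
        if parts and parts[0] == "circular" and circular is None:
            is_circular = _parse_bool(parts[1])
    if genome_length is None:
        raise AnnotationError("GFF3 lacks a ##sequence-region directive")

    genes, promoters, terminators = [], [], []
    for feat in db.all_features():
        attrs = {k: v[0] for k, v in feat.attributes.items()}
        start0, end0 = feat.start - 1, feat.end  # 1-based closed -> half-open
        if feat.strand not in _STRANDS:
            raise AnnotationError(f"feature at {feat.start}: unknown strand {feat.strand!r}")
        if end0 > genome_length or start0 < 0:
            raise AnnotationError(
                f"feature {feat.start}..{feat.end} outside genome of length {genome_length}"
            )
        mid = (start0 + end0 - 1) // 2
        if feat.featuretype == "gene":
            genes.append(
                Gene(
                    id=attrs.get("ID", f"gene_{start0}"),
                    start=start0,
                    end=end0,
                    strand=feat.strand,
                    essential=_parse_bool(attrs.get("essential", "false")),
                )
            )
        elif feat.featuretype == "promoter":
            promoters.append(
                Promoter(
                    pos=mid,
                    strand=feat.strand,
                    primary=attrs.get("class", "primary") == "primary",
                )
            )
        elif feat.featuretype == "terminator":
            mode = attrs.get("mode", "intrinsic")
            terminators.append(Terminator(pos=mid, strand=feat.strand, mode=mode))
    return AnnotationBundle(
        genome_length=genome_length,
        circular=is_circular,
        genes=genes,
        promoters=promoters,
        terminators=terminators,
        seqid=seqid,
    )


def _read_annotation_tsv(
    genes_tsv: str | Path,
    promoters_tsv: str | Path,
    terminators_tsv: str | Path,
    genome_length: int,
    circular: bool,
) -> AnnotationBundle:
    g = pd.read_csv(genes_tsv, sep="\t")
    p = pd.read_csv(promoters_tsv, sep="\t")
    t = pd.read_csv(terminators_tsv, sep="\t")
    genes = [
        Gene(str(r.id), int(r.start), int(r.end), str(r.strand), bool(r.essential))
        for r in g.itertuples()
    ]
    promoters = [
        Promoter(int(r.pos), str(r.strand), bool(r.primary)) for r in p.itertuples()
    ]
    terminators = [
        Terminator(int(r.pos), str(r.strand), str(r.mode)) for r in t.itertuples()
    ]
    return AnnotationBundle(
        genome_length=genome_length,
        circular=circular,
        genes=genes,
        promoters=promoters,
        terminators=terminators,
    )


def read_annotation(
    path: str | Path | None = None,
    *,
    genes_tsv: str | Path | None = None,
    promoters_tsv: str | Path | None = None,
    terminators_tsv: str | Path | None = None,
    genome_length: int | None = None,
    circular: bool | None = None,
    sequence: str | None = None,
) -> AnnotationBundle:
    """Read an annotation as GFF3 (``path``) or as a 3-table TSV set.

    GFF3 coordinates (1-based closed) are converted to internal 0-based
    half-open; point features (promoters, terminators) are reduced to their
    interval midpoint. TSV tables are already in internal coordinates.
    """
    if path is not None:
        bundle = _read_annotation_gff3(path, circular)
    else:
        if None in (genes_tsv, promoters_tsv, terminators_tsv, genome_length):
            raise AnnotationError("TSV mode needs all three tables and genome_length")
        bundle = _read_annotation_tsv(
            genes_tsv, promoters_tsv, terminators_tsv, genome_length,
            True if circular is None else circular,
        )
    if sequence is not None:
        bundle = replace(bundle, sequence=sequence)
    return bundle


def write_annotation_gff3(bundle: AnnotationBundle, path: str | Path) -> None:
    """Write an annotation bundle as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {bundle.seqid} 1 {bundle.genome_length}\n")
        fh.write(f"##circular {'true' if bundle.circular else 'false'}\n")
        rows = []
        for g in bundle.genes:
            rows.append(
                (g.start, f"{bundle.seqid}\trescuemap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                 f"{g.strand}\t.\tID={g.id};essential={'true' if g.essential else 'false'}")
            )
        for p in bundle.promoters:
            rows.append(
                (p.pos, f"{bundle.seqid}\trescuemap\tpromoter\t{p.pos + 1}\t{p.pos + 1}\t.\t"
                 f"{p.strand}\t.\tclass={'primary' if p.primary else 'secondary'}")
            )
        for t in bundle.terminators:
            rows.append(
                (t.pos, f"{bundle.seqid}\trescuemap\tterminator\t{t.pos + 1}\t{t.pos + 1}\t.\t"
                 f"{t.strand}\t.\tmode={t.mode}")
            )
        for _, line in sorted(rows, key=lambda r: r[0]):
            fh.write(line + "\n")


def write_bed(
    regions: Sequence[tuple[int, int]],
    path: str | Path,
    *,
    chrom: str = "chrom",
    names: Sequence[str] | None = None,
) -> None:
    """Write internal 0-based half-open intervals as BED (no coordinate shift)."""
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(regions):
            fields = [chrom, str(start), str(end)]
            if names is not None:
                fields.append(names[i])
            fh.write("\t".join(fields) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


@dataclass
class QpcrRecord:
    """Mean quantification cycles for one sample on the target and reference
    assays, with per-assay amplification efficiency as a fraction in (0, 1]
    (1.0 = 100%, i.e. perfect doubling per cycle)."""

    sample_id: str
    cq_target: float
    cq_reference: float
    efficiency_target: float
    efficiency_reference: float
    sd_target: float = 0.0
    sd_reference: float = 0.0
    n_target: int = 1
    n_reference: int = 1

    def __post_init__(self) -> None:
        for name, cq in (("target", self.cq_target), ("reference", self.cq_reference)):
            if not (math.isfinite(cq) and cq > 0):
                raise ValueError(f"{self.sample_id}: Cq_{name} must be finite and positive")
        for name, e in (
            ("target", self.efficiency_target),
            ("reference", self.efficiency_reference),
        ):
            if not (0 < e <= 1):
                raise ValueError(
                    f"{self.sample_id}: efficiency_{name} must be in (0, 1], got {e}"
                )


_QPCR_COLUMNS = ["sample", "assay", "cq", "efficiency"]


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Read a long qPCR table (columns ``sample, assay, cq, efficiency``);
    one row per technical replicate."""
    df = pd.read_csv(path)
    missing = [c for c in _QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR CSV missing column(s): {', '.join(missing)}")
    return df


def qpcr_records_from_table(
    df: pd.DataFrame, *, target_assay: str, reference_assay: str
) -> list[QpcrRecord]:
    """Aggregate technical replicates (mean Cq, SD) into one
    :class:`QpcrRecord` per sample."""
    records = []
    for sample, grp in df.groupby("sample", sort=True):
        tgt = grp[grp["assay"] == target_assay]
        ref = grp[grp["assay"] == reference_assay]
        if tgt.empty or ref.empty:
            raise ValueError(f"sample {sample}: missing target or reference assay rows")
        records.append(
            QpcrRecord(
                sample_id=str(sample),
                cq_target=float(tgt["cq"].mean()),
                cq_reference=float(ref["cq"].mean()),
                efficiency_target=float(tgt["efficiency"].iloc[0]),
                efficiency_reference=float(ref["efficiency"].iloc[0]),
                sd_target=float(tgt["cq"].std(ddof=1)) if len(tgt) > 1 else 0.0,
                sd_reference=float(ref["cq"].std(ddof=1)) if len(ref) > 1 else 0.0,
                n_target=len(tgt),
                n_reference=len(ref),
            )
        )
    return records


def write_qpcr_csv(estimates, path: str | Path) -> None:
    """Write copy-number estimates as CSV (``sample, copy_number, sd``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "copy_number", "sd"])
        for est in estimates:
            w.writerow([est.sample_id, repr(est.copy_number), repr(est.replicate_sd)])
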