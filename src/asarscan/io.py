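"""Readers and writers for BED, GFF3/GTF, RepeatMasker .out and bedGraph.

Every reader is gzip-transparent (a ``.gz`` suffix or gzip magic bytes are
detected automatically).  Internally everything is 0-based half-open; the
1-based closed conventions of GFF3/GTF and RepeatMasker are converted at the
boundary and nowhere else.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np

from .coverage import CoverageTrack
from .intervals import Feature, FeatureSet, GenomicInterval

__all__ = [
    "read_features",
    "read_coverage",
    "write_bed",
    "write_bedgraph",
    "ParseError",
]

FORMATS = {"bed", "gff3", "gtf", "rmsk_out"}


class ParseError(ValueError):
    """Malformed input line; carries the file and 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _open_text(path: str | Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line


# --------------------------------------------------------------------------
# feature readers


def read_features(
    path: str | Path, format: str, genome: dict[str, int] | None = None
) -> FeatureSet:
    """Read an annotation file into a :class:`FeatureSet`.

    ``format`` is one of ``bed``, ``gff3``, ``gtf``, ``rmsk_out``.  BED input
    is kept as-is (already 0-based half-open); GFF3/GTF and RepeatMasker rows
    are shifted from 1-based closed to 0-based half-open.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(FORMATS)}")
    reader = {
        "bed": _read_bed,
        "gff3": _read_gxf,
        "gtf": _read_gxf,
        "rmsk_out": _read_rmsk,
    }[format]
    features = list(reader(path, format))
    return FeatureSet(features, genome or {})


def _read_bed(path: str | Path, _format: str) -> Iterator[Feature]:
    for lineno, line in _lines(path):
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError(path, lineno, "BED needs at least 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        name = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
        # name column may carry "kind:family" emitted by write_bed
        kind, family = "domain", ""
        if ":" in name:
            maybe_kind, _, rest = name.partition(":")
            if maybe_kind in {"gene", "exon", "intron", "repeat", "domain"}:
                kind = maybe_kind
                family, _, name = rest.partition("|")
        try:
            iv = GenomicInterval(chrom, start, end, strand)
            yield Feature(iv, kind, family=family, name=name)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None


_ATTR_GTF = re.compile(r'(\w+)\s+"([^"]*)"')


def _gxf_attrs(col: str, fmt: str) -> dict[str, str]:
    if fmt == "gtf":
        return dict(_ATTR_GTF.findall(col))
    out = {}
    for item in col.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gxf(path: str | Path, fmt: str) -> Iterator[Feature]:
    kind_map = {"gene": "gene", "exon": "exon", "intron": "intron"}
    for lineno, line in _lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(path, lineno, f"{fmt.upper()} needs 9 columns, got {len(fields)}")
        chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
        kind = kind_map.get(ftype)
        if kind is None:
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        attrs = _gxf_attrs(attrs_s, fmt)
        family = (
            attrs.get("gene_biotype")
            or attrs.get("biotype")
            or attrs.get("gene_type", "")
        )
        name = attrs.get("gene_id") or attrs.get("ID") or attrs.get("Parent", "")
        try:
            iv = GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            yield Feature(iv, kind, family=family, name=name)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None


def _read_rmsk(path: str | Path, _format: str) -> Iterator[Feature]:
    """RepeatMasker .out: two header lines then whitespace-delimited rows."""
    for lineno, line in _lines(path):
        fields = line.split()
        if not fields or not fields[0].lstrip("-").isdigit():
            continue  # header / separator lines
        if len(fields) < 11:
            raise ParseError(path, lineno, "RepeatMasker row needs >= 11 columns")
        chrom = fields[4]
        try:
            start1, end1 = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        strand = "-" if fields[8] == "C" else "+"
        name = fields[9]
        family = fields[10]  # repClass/repFamily token, e.g. LINE/L1
        try:
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            yield Feature(iv, "repeat", family=family, name=name)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None


# --------------------------------------------------------------------------
# coverage


def read_coverage(
    path: str | Path,
    genome: dict[str, int] | None = None,
    strand: str = ".",
) -> CoverageTrack:
    """Read a bedGraph file into a dense :class:`CoverageTrack`.

    Positions absent from the file get depth 0.  Overlapping records with
    conflicting values raise; identical restatements are tolerated.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    maxend: dict[str, int] = {}
    for lineno, line in _lines(path):
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ParseError(path, lineno, "bedGraph needs 4 columns")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad bedGraph record: {exc}") from None
        if value < 0:
            raise ParseError(path, lineno, "negative depth")
        if not 0 <= start < end:
            raise ParseError(path, lineno, f"bad interval [{start}, {end})")
        records.setdefault(chrom, []).append((start, end, value))
        maxend[chrom] = max(maxend.get(chrom, 0), end)

    data: dict[str, np.ndarray] = {}
    sizes = dict(genome or {})
    for chrom, recs in records.items():
        n = sizes.get(chrom, maxend[chrom])
        vec = np.zeros(n)
        seen = np.zeros(n, dtype=bool)
        for start, end, value in recs:
            if end > n:
                raise ValueError(f"record [{start},{end}) exceeds {chrom} length {n}")
            clash = seen[start:end] & (vec[start:end] != value)
            if clash.any():
                raise ValueError(
                    f"overlapping bedGraph records with conflicting values on "
                    f"{chrom} at [{start},{end})"
                )
            vec[start:end] = value
            seen[start:end] = True
        data[chrom] = vec
    for chrom, n in sizes.items():
        data.setdefault(chrom, np.zeros(n))
    return CoverageTrack(data, strand=strand)


# --------------------------------------------------------------------------
# writers


def write_bed(features: FeatureSet | Iterable[Feature], path: str | Path) -> None:
    """Write features as BED6; kind and family are encoded in the name column
    (``kind:family|name``) so a write/read round trip is lossless."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for f in features:
            iv = f.interval
            name = f"{f.kind}:{f.family}|{f.name}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length-compressing constant stretches
    and omitting zero runs."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for chrom in track.chroms():
            vec = track.depth(chrom)
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    val = int(v) if float(v).is_integer() else v
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")
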