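"""Alignment readers/writers (FASTA, PHYLIP sequential, NEXUS) and the HTML
trimming report.

FASTA and NEXUS go through Biopython; the PHYLIP-sequential reader is a small
relaxed-dialect parser (whitespace-delimited identifiers of any length), while
writing emits the strict 10-character dialect for interoperability.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from html import escape
from pathlib import Path
from typing import TextIO, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment, SeqType

__all__ = [
    "read_alignment",
    "write_alignment",
    "TrimReport",
    "write_html_report",
    "FormatError",
]

Source = Union[str, Path, TextIO]


class FormatError(ValueError):
    """The input cannot be parsed in the requested format."""


def _as_handle(source: Source) -> TextIO:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            return open(p)
        if isinstance(source, str) and ("\n" in source or source.startswith(">")):
            return _io.StringIO(source)
        raise FileNotFoundError(source)
    return source


def _read_fasta(handle: TextIO) -> list[tuple[str, str]]:
    try:
        records = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")
        ]
    except ValueError as exc:
        raise FormatError(f"malformed FASTA input: {exc}") from exc
    if not records:
        raise FormatError("no FASTA records found (empty or malformed input)")
    return records


def _read_phylip_sequential(handle: TextIO) -> list[tuple[str, str]]:
    """Relaxed sequential PHYLIP: header ``n m``, then whitespace-delimited
    name followed by the sequence, which may continue on subsequent lines."""
    lines = [ln.rstrip("\n") for ln in handle]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError("empty PHYLIP input")
    header = lines[0].split()
    if len(header) < 2:
        raise FormatError(f"bad PHYLIP header line {lines[0]!r}")
    try:
        n, m = int(header[0]), int(header[1])
    except ValueError as exc:
        raise FormatError(f"bad PHYLIP header line {lines[0]!r}") from exc
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for ln in lines[1:]:
        if name is None:
            parts = ln.split(None, 1)
            name = parts[0]
            chunks = [parts[1].replace(" ", "") if len(parts) > 1 else ""]
        else:
            chunks.append(ln.replace(" ", ""))
        seq = "".join(chunks)
        if len(seq) >= m:
            if len(seq) > m:
                raise FormatError(
                    f"sequence {name!r} longer ({len(seq)}) than declared {m}"
                )
            records.append((name, seq))
            name, chunks = None, []
    if name is not None:
        records.append((name, "".join(chunks)))
    if len(records) != n:
        raise FormatError(
            f"PHYLIP header declares {n} sequences but {len(records)} were read"
        )
    return records


def read_alignment(
    source: Source, format: str = "fasta", seq_type: SeqType | str = SeqType.DNA
) -> Alignment:
    """Read a multiple sequence alignment.

    Parameters
    ----------
    source:
        Path, raw text, or an open text handle.
    format:
        ``"fasta"`` or ``"phylip"`` (sequential, relaxed identifiers).
    seq_type:
        Declared alphabet; the caller must state whether sequences are DNA,
        amino acids, or DNA to be read as in-frame codons.
    """
    seq_type = SeqType(seq_type)
    handle = _as_handle(source)
    fmt = format.lower().replace("-sequential", "")
    if fmt == "fasta":
        records = _read_fasta(handle)
    elif fmt == "phylip":
        records = _read_phylip_sequential(handle)
    else:
        raise FormatError(f"unsupported input format {format!r}")
    return Alignment(records, seq_type)


def _nexus_datatype(seq_type: SeqType) -> str:
    return "protein" if seq_type is SeqType.AA else "dna"


def write_alignment(aln: Alignment, format: str = "fasta") -> str:
    """Serialize an alignment to FASTA, sequential PHYLIP, or NEXUS text.

    Sequence and column order are preserved exactly.  PHYLIP names are padded
    or truncated to 10 characters (a warning is issued on truncation)."""
    fmt = format.lower().replace("-sequential", "")
    if fmt == "fasta":
        out = _io.StringIO()
        SeqIO.write(
            (SeqRecord(Seq(seq), id=ident, description="")
             for ident, seq in aln.records),
            out,
            "fasta",
        )
        return out.getvalue()
    if fmt == "phylip":
        lines = [f" {aln.n} {aln.m}"]
        for ident, seq in aln.records:
            if len(ident) > 10:
                warnings.warn(
                    f"PHYLIP identifier {ident!r} truncated to 10 characters"
                )
            lines.append(f"{ident[:10]:<10}  {seq}")
        return "\n".join(lines) + "\n"
    if fmt == "nexus":
        dt = _nexus_datatype(aln.seq_type)
        lines = [
            "#NEXUS",
            "begin data;",
            f"  dimensions ntax={aln.n} nchar={aln.m};",
            f"  format datatype={dt} gap=- missing=?;",
            "  matrix",
        ]
        width = max(len(i) for i in aln.identifiers)
        for ident, seq in aln.records:
            lines.append(f"  {ident:<{width}}  {seq}")
        lines += ["  ;", "end;"]
        return "\n".join(lines) + "\n"
    raise FormatError(f"unsupported output format {format!r}")


# ---------------------------------------------------------------------------
# Trimming report
# ---------------------------------------------------------------------------

@dataclass
class TrimReport:
    """Outcome of a trimming run over an ``m``-column alignment.

    Column indices are 1-based; ``kept_columns`` and ``removed_columns``
    partition ``1..m``.  ``h_smooth`` and ``g`` are the per-column smoothed
    entropy-like scores and gap proportions (aligned with columns 1..m of the
    scored alignment).  ``regions`` holds the final conserved/variable runs as
    ``(start, end, kind)`` with kind ``"C"`` or ``"V"``.
    """

    m: int
    kept_columns: list[int]
    removed_columns: list[int]
    h_smooth: np.ndarray | None = None
    g: np.ndarray | None = None
    regions: list[tuple[int, int, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept, removed = set(self.kept_columns), set(self.removed_columns)
        if kept | removed != set(range(1, self.m + 1)) or kept & removed:
            raise ValueError("kept/removed columns do not partition 1..m")
        self.kept_columns = sorted(kept)
        self.removed_columns = sorted(removed)

    @classmethod
    def from_mask(cls, mask: np.ndarray, **kwargs) -> "TrimReport":
        mask = np.asarray(mask, dtype=bool)
        idx = np.arange(1, mask.size + 1)
        return cls(
            m=mask.size,
            kept_columns=idx[mask].tolist(),
            removed_columns=idx[~mask].tolist(),
            **kwargs,
        )

    @property
    def mask(self) -> np.ndarray:
        mask = np.zeros(self.m, dtype=bool)
        mask[np.asarray(self.kept_columns, dtype=int) - 1] = True
        return mask


_HTML_CSS = """
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; font-size: 11px; }
td, th { border: 1px solid #ccc; padding: 1px 4px; text-align: right; }
tr.kept { background: #e6f4e6; }
tr.removed { background: #f8e0e0; }
.bar { display: inline-block; height: 9px; background: #4477aa; }
.gapbar { display: inline-block; height: 9px; background: #cc6677; }
"""


def write_html_report(aln: Alignment, report: TrimReport) -> str:
    """Render an HTML document showing, per column, the smoothed entropy-like
    score and gap proportion, visually distinguishing selected (kept) from
    removed columns."""
    if report.m != aln.m:
        raise ValueError(
            f"report covers {report.m} columns but alignment has {aln.m}"
        )
    kept = set(report.kept_columns)
    n_kept = len(kept)
    h = report.h_smooth
    g = report.g
    rows = []
    for c in range(1, aln.m + 1):
        cls = "kept" if c in kept else "removed"
        status = "selected" if c in kept else "removed"
        hval = "" if h is None else f"{float(h[c - 1]):.4g}"
        gval = "" if g is None else f"{float(g[c - 1]):.4g}"
        hbar = "" if h is None else (
            f'<span class="bar" style="width:{float(h[c-1])*100:.0f}px"></span>'
        )
        gbar = "" if g is None else (
            f'<span class="gapbar" style="width:{float(g[c-1])*100:.0f}px"></span>'
        )
        rows.append(
            f'<tr class="{cls}"><td>{c}</td><td>{status}</td>'
            f"<td>{hval}</td><td>{hbar}</td><td>{gval}</td><td>{gbar}</td></tr>"
        )
    region_txt = ", ".join(
        f"{kind}({start}-{end})" for start, end, kind in report.regions
    ) or "n/a"
    params_txt = escape(
        ", ".join(f"{k}={v}" for k, v in report.params.items()) or "defaults"
    )
    summary = (
        f"{n_kept} of {aln.m} characters selected"
        if n_kept
        else f"0 selected characters (all {aln.m} removed)"
    )
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Alignment trimming report</title>
<style>{_HTML_CSS}</style></head>
<body>
<h1>Alignment trimming report</h1>
<p>{aln.n} sequences &times; {aln.m} columns ({escape(aln.seq_type.value)});
{summary}.</p>
<p>Parameters: {params_txt}</p>
<p>Regions: {escape(region_txt)}</p>
<table>
<tr><th>column</th><th>status</th><th>h&#771;</th><th>entropy</th>
<th>gap</th><th>gap prop.</th></tr>
{chr(10).join(rows)}
</table>
</body></html>
"""
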