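"""FASTA input, alignment serialization and special-row checkpoints.

Alignments round-trip through either format: ``gapped-fasta`` (two records
of equal length with '-' gaps, metadata on the headers) or ``tsv-pairs``
(one row per column with 1-based coordinates and a match/mismatch/gap
class).  Special-row checkpoints are TSV with a trailing SHA-256 line so a
corrupt or truncated file is rejected rather than silently reused.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from Bio import SeqIO

from .core import (
    Alignment,
    CheckpointError,
    FormatError,
    IntegrityError,
    Sequence,
    SpecialRows,
)

PathLike = Union[str, Path]

ALIGNMENT_FORMATS = ("gapped-fasta", "tsv-pairs")


def read_fasta(path: PathLike) -> List[Sequence]:
    """All records of a FASTA file as normalized (uppercased) Sequences.

    Streams record by record; accepts CRLF and multi-line records.
    """
    seqs: List[Sequence] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs.append(Sequence(rec.id, str(rec.seq)))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: List[Sequence], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for off in range(0, len(s.residues), width):
                fh.write(s.residues[off : off + width] + "\n")


def _column_class(top: str, bot: str) -> str:
    if top == "-" or bot == "-":
        return "gap"
    return "match" if top == bot else "mismatch"


def write_alignment(
    aln: Alignment,
    path: PathLike,
    format: str = "gapped-fasta",
    ids: Tuple[str, str] = ("S0", "S1"),
) -> None:
    if format not in ALIGNMENT_FORMATS:
        raise FormatError(f"unknown alignment format {format!r}")
    meta = (
        f"mode={aln.mode} gap_model={aln.gap_model} score={aln.score}"
    )
    with open(path, "w") as fh:
        if format == "gapped-fasta":
            top = "".join(t for t, _ in aln.columns)
            bot = "".join(b for _, b in aln.columns)
            fh.write(f">{ids[0]} start={aln.start0} end={aln.end0} {meta}\n")
            fh.write(top + "\n")
            fh.write(f">{ids[1]} start={aln.start1} end={aln.end1}\n")
            fh.write(bot + "\n")
        else:
            fh.write(
                f"# stagealign tsv-pairs {meta} "
                f"start0={aln.start0} end0={aln.end0} "
                f"start1={aln.start1} end1={aln.end1}\n"
            )
            fh.write("pos0\tres0\tpos1\tres1\tclass\n")
            i, j = aln.start0, aln.start1
            for top, bot in aln.columns:
                p0 = str(i) if top != "-" else "-"
                p1 = str(j) if bot != "-" else "-"
                fh.write(f"{p0}\t{top}\t{p1}\t{bot}\t{_column_class(top, bot)}\n")
                if top != "-":
                    i += 1
                if bot != "-":
                    j += 1


def _parse_meta(tokens: List[str]) -> Dict[str, str]:
    out = {}
    for tok in tokens:
        if "=" in tok:
            key, val = tok.split("=", 1)
            out[key] = val
    return out


def read_alignment(path: PathLike, format: str = "gapped-fasta") -> Alignment:
    if format not in ALIGNMENT_FORMATS:
        raise FormatError(f"unknown alignment format {format!r}")
    text = Path(path).read_text()
    lines = [ln.rstrip("\r\n") for ln in text.splitlines()]
    if format == "gapped-fasta":
        heads = [k for k, ln in enumerate(lines) if ln.startswith(">")]
        if len(heads) != 2:
            raise FormatError(f"expected 2 gapped-fasta records in {path}")
        meta0 = _parse_meta(lines[heads[0]].split())
        meta1 = _parse_meta(lines[heads[1]].split())
        top = "".join(lines[heads[0] + 1 : heads[1]])
        bot = "".join(lines[heads[1] + 1 :])
        if len(top) != len(bot):
            raise FormatError("gapped records differ in length")
        return Alignment(
            columns=list(zip(top, bot)),
            score=int(meta0["score"]),
            start0=int(meta0["start"]),
            end0=int(meta0["end"]),
            start1=int(meta1["start"]),
            end1=int(meta1["end"]),
            mode=meta0["mode"],
            gap_model=meta0["gap_model"],
        )
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"missing tsv-pairs header in {path}")
    meta = _parse_meta(lines[0].split())
    columns = []
    for ln in lines[2:]:
        if not ln:
            continue
        _, top, _, bot, _ = ln.split("\t")
        columns.append((top, bot))
    return Alignment(
        columns=columns,
        score=int(meta["score"]),
        start0=int(meta["start0"]),
        end0=int(meta["end0"]),
        start1=int(meta["start1"]),
        end1=int(meta["end1"]),
        mode=meta["mode"],
        gap_model=meta["gap_model"],
    )


def write_special_rows(specials: SpecialRows, path: PathLike) -> None:
    """Persist one partition's checkpoint rows with a trailing checksum."""
    body_lines = [
        f"# stagealign-specials interval={specials.interval} "
        f"j_lo={specials.j_lo} j_hi={specials.j_hi}"
    ]
    for r in sorted(specials.rows):
        h, f = specials.rows[r]
        body_lines.append(f"{r}\th\t{','.join(str(int(v)) for v in h)}")
        if f is not None:
            body_lines.append(f"{r}\tf\t{','.join(str(int(v)) for v in f)}")
    body = "\n".join(body_lines) + "\n"
    digest = hashlib.sha256(body.encode()).hexdigest()
    with open(path, "w") as fh:
        fh.write(body)
        fh.write(f"# sha256={digest}\n")
    specials.path = str(path)


def read_special_rows(path: PathLike) -> SpecialRows:
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"empty special-rows checkpoint {path}")
    lines = text.splitlines()
    if not lines[-1].startswith("# sha256="):
        raise IntegrityError(f"missing checksum in {path}")
    digest = lines[-1].split("=", 1)[1].strip()
    body = "\n".join(lines[:-1]) + "\n"
    if hashlib.sha256(body.encode()).hexdigest() != digest:
        raise IntegrityError(f"checksum mismatch in {path}")
    meta = _parse_meta(lines[0].split())
    try:
        interval = int(meta["interval"])
        j_lo, j_hi = int(meta["j_lo"]), int(meta["j_hi"])
    except KeyError as exc:
        raise CheckpointError(f"missing {exc} in checkpoint header") from exc
    rows: Dict[int, Tuple[np.ndarray, Optional[np.ndarray]]] = {}
    frows: Dict[int, np.ndarray] = {}
    for ln in lines[1:-1]:
        r_s, kind, payload = ln.split("\t")
        vals = np.array([int(v) for v in payload.split(",")], dtype=np.int64)
        if kind == "h":
            rows[int(r_s)] = (vals, None)
        elif kind == "f":
            frows[int(r_s)] = vals
        else:
            raise CheckpointError(f"unknown row kind {kind!r}")
    for r, f in frows.items():
        if r not in rows:
            raise CheckpointError(f"F row {r} without H row")
        rows[r] = (rows[r][0], f)
    if not rows:
        raise FormatError(f"no checkpoint rows in {path}")
    return SpecialRows(interval=interval, j_lo=j_lo, j_hi=j_hi, rows=rows, path=str(path))
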