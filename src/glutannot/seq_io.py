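"""FASTA input/output, ORF translation, and tabular reports.

High molecular weight glutenin subunit (HMW-GS) genes are intronless, so a
gene is handled as a single open reading frame (ORF) plus an optional
5'-flanking promoter sequence.  Promoter records travel in the same FASTA as
the ORFs and are paired by an id convention: a record named ``<id>_prom``
supplies the promoter of the ORF record named ``<id>``.

Translation policy
------------------
HMW-GS ORFs conventionally end with a tandem pair of stop codons (the 3'
cloning primer for these genes encodes TGA TAG), so up to two trailing
in-frame stops are consumed and counted rather than treated as errors.  An
in-frame stop followed by further coding sequence marks the record as
pseudogene-like; translation is returned up to that stop with a warning
status.  Any codon containing N translates to X.

All coordinates in written reports are 1-based inclusive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
PROMOTER_SUFFIX = "_prom"

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
MAX_TRAILING_STOPS = 2


class FastaError(ValueError):
    """Malformed FASTA input (duplicate ids, empty file, illegal characters)."""


class TranslationError(ValueError):
    """ORF violates the translation preconditions (length, start codon, frame)."""


@dataclass
class GeneRecord:
    """A HMW-GS gene: coding ORF plus optional 5'-flanking promoter."""

    id: str
    orf_dna: str
    promoter_dna: str | None = None
    source: str = ""


@dataclass
class ProteinSeq:
    id: str
    residues: str


@dataclass
class TranslationResult:
    protein: ProteinSeq
    n_codons: int            # raw codon count of the ORF, stops included
    n_trailing_stops: int
    status: str              # "ok" | "premature_stop"
    message: str = ""


def _find_illegal_line(path: Path, alphabet: frozenset[str]) -> int:
    """Return the 1-based line number of the first line with an illegal character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            bad = set(line.strip().upper()) - alphabet
            if bad:
                return lineno
    return -1


def read_fasta(path: str | Path, kind: str = "dna") -> list[GeneRecord] | list[ProteinSeq]:
    """Read a FASTA file into :class:`GeneRecord` or :class:`ProteinSeq` objects.

    Sequences are upper-cased; record order is preserved; ids must be unique.
    ``kind`` is ``"dna"`` (ACGTN alphabet) or ``"protein"``.
    """
    path = Path(path)
    if kind not in ("dna", "protein"):
        raise ValueError(f"kind must be 'dna' or 'protein', got {kind!r}")
    alphabet = DNA_ALPHABET if kind == "dna" else PROTEIN_ALPHABET
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - alphabet
        if bad:
            lineno = _find_illegal_line(path, alphabet)
            raise FastaError(
                f"{path}:{lineno}: illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        if kind == "dna":
            records.append(GeneRecord(id=rec.id, orf_dna=seq, source=str(path)))
        else:
            records.append(ProteinSeq(id=rec.id, residues=seq))
    if not records:
        raise FastaError(f"{path}: empty FASTA file")
    return records


def pair_promoters(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Merge ``<id>_prom`` records into the ``promoter_dna`` of their ORF record.

    Returns the ORF records in input order.  A promoter record without a
    matching ORF record is an error.
    """
    orfs = {r.id: r for r in records if not r.id.endswith(PROMOTER_SUFFIX)}
    out = [r for r in records if not r.id.endswith(PROMOTER_SUFFIX)]
    for rec in records:
        if rec.id.endswith(PROMOTER_SUFFIX):
            target = rec.id[: -len(PROMOTER_SUFFIX)]
            if target not in orfs:
                raise FastaError(f"promoter record {rec.id!r} has no ORF record {target!r}")
            orfs[target].promoter_dna = rec.orf_dna
    return out


def write_fasta(records: Iterable[GeneRecord | ProteinSeq], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.orf_dna if isinstance(rec, GeneRecord) else rec.residues
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if isinstance(rec, GeneRecord) and rec.promoter_dna:
                fh.write(f">{rec.id}{PROMOTER_SUFFIX}\n")
                for i in range(0, len(rec.promoter_dna), width):
                    fh.write(rec.promoter_dna[i : i + width] + "\n")


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def translate_orf(orf_dna: str, id: str = "orf") -> TranslationResult:
    """Translate an ORF under the HMW-GS stop-trimming policy (see module docs)."""
    orf_dna = orf_dna.upper()
    if len(orf_dna) < 3:
        raise TranslationError(f"{id}: ORF shorter than one codon")
    if not orf_dna.startswith("ATG"):
        raise TranslationError(f"{id}: ORF does not begin with ATG")
    if len(orf_dna) % 3 != 0:
        raise TranslationError(f"{id}: ORF length {len(orf_dna)} not a multiple of 3")
    codons = [orf_dna[i : i + 3] for i in range(0, len(orf_dna), 3)]
    aas = [_translate_codon(c) for c in codons]
    try:
        first_stop = aas.index("*")
    except ValueError:
        return TranslationResult(ProteinSeq(id, "".join(aas)), len(codons), 0, "ok")
    tail = aas[first_stop:]
    if all(a == "*" for a in tail) and len(tail) <= MAX_TRAILING_STOPS:
        return TranslationResult(
            ProteinSeq(id, "".join(aas[:first_stop])), len(codons), len(tail), "ok"
        )
    # count the run of stops at the premature position, for the report
    run = 0
    for a in tail:
        if a != "*":
            break
        run += 1
    return TranslationResult(
        ProteinSeq(id, "".join(aas[:first_stop])),
        len(codons),
        run,
        "premature_stop",
        message=f"{id}: in-frame stop at codon {first_stop + 1} of {len(codons)}; "
        "translation truncated (pseudogene-like)",
    )


# ---------------------------------------------------------------------------
# Tabular reports (Table-2 / Table-4 shaped output)

_HEADER_NOTE = "coordinates are 1-based inclusive"


def write_report(
    rows: Sequence[dict],
    path: str | Path,
    format: str = "tsv",
    meta: dict | None = None,
) -> None:
    """Write annotation rows as TSV (with # header comments) or JSON.

    Output is bit-stable for identical inputs: column order is taken from the
    first row, JSON keys are sorted, and no timestamps are embedded.
    """
    meta = dict(meta or {})
    meta.setdefault("note", _HEADER_NOTE)
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for k in sorted(meta):
                fh.write(f"# {k}: {meta[k]}\n")
            if rows:
                cols = list(rows[0].keys())
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump({"meta": meta, "rows": list(rows)}, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> tuple[dict, list[dict]]:
    """Read a report back; TSV values come back as strings."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            obj = json.load(fh)
        return obj["meta"], obj["rows"]
    meta: dict = {}
    rows: list[dict] = []
    cols: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                k, _, v = line[2:].partition(": ")
                meta[k] = v
            elif cols is None:
                cols = line.split("\t")
            elif line:
                rows.append(dict(zip(cols, line.split("\t"))))
    return meta, rows
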