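"""Multi-gene supermatrix assembly, coverage reporting, partition export.

Implements the study's sequence-selection rules: per taxon and gene the
longest sequence (most non-missing characters) wins; among length ties
records flagged as preferred-region origin win; remaining ties fall to
the lexicographically smallest source id, making selection a total
order.  Missing whole-gene blocks are filled with ``?`` (unknown), kept
distinct from the alignment gap ``-`` (deletion).

Column ranges in exported charsets are 1-based inclusive (the convention
of the partition formats this feeds); internal arithmetic is 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, ContractError

#: Characters that carry no information for "longest sequence" purposes.
MISSING_CHARS = frozenset("-?Nn")


@dataclass(frozen=True)
class SequenceRecord:
    """One candidate sequence for a taxon × gene cell."""

    taxon: str
    seq: str
    preferred_origin: bool = False
    source_id: str = ""

    def informative_length(self) -> int:
        return sum(1 for ch in self.seq if ch not in MISSING_CHARS)


@dataclass
class GeneAlignment:
    """One aligned gene: equal-length rows over {A,C,G,T,N,-,?}.

    ``coding_in_frame`` means column 1 is codon position 1, which is what
    codon partitioning needs; fragment lengths need not be multiples of
    three.
    """

    name: str
    records: list[SequenceRecord]
    coding_in_frame: bool = True

    def __post_init__(self) -> None:
        if not self.records:
            raise ContractError(f"gene {self.name!r} has no sequences")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ContractError(
                f"gene {self.name!r}: unequal aligned lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def taxa(self) -> list[str]:
        return [r.taxon for r in self.records]


def select_sequence(candidates: Sequence[SequenceRecord]) -> SequenceRecord:
    """Pick the winning candidate for one taxon × gene cell.

    Longest (most non-missing characters) first; among ties,
    preferred-origin records; then smallest source id.  Deterministic
    under any input permutation.
    """
    if not candidates:
        raise ContractError("no candidate sequences to select from")
    return min(
        candidates,
        key=lambda r: (-r.informative_length(), not r.preferred_origin, r.source_id),
    )


@dataclass
class Supermatrix:
    """Concatenated alignment with per-gene column blocks.

    ``blocks`` holds ``(gene name, start, end)`` with 1-based inclusive
    columns tiling ``[1, length]`` in input gene order.
    """

    taxa: list[str]
    sequences: dict[str, str]
    blocks: list[tuple[str, int, int]]
    coding_in_frame: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.blocks[-1][2] if self.blocks else 0


def concatenate(genes: Sequence[GeneAlignment], taxa: Sequence[str]) -> Supermatrix:
    """Concatenate gene alignments over a fixed taxon list.

    Every taxon gets one row; a taxon absent from a gene receives a
    block of ``?``.  A taxon occurring twice within one gene is an
    error (selection must happen first; see :func:`select_sequence`).
    """
    names = [g.name for g in genes]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate gene names: {names}")
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ConfigError("duplicate taxa in taxon list")
    per_gene: list[dict[str, str]] = []
    for g in genes:
        rows: dict[str, str] = {}
        for rec in g.records:
            if rec.taxon in rows:
                raise ConfigError(
                    f"taxon {rec.taxon!r} occurs twice in gene {g.name!r}"
                )
            rows[rec.taxon] = rec.seq
        per_gene.append(rows)
    blocks: list[tuple[str, int, int]] = []
    start = 1
    for g in genes:
        blocks.append((g.name, start, start + g.length - 1))
        start += g.length
    sequences = {}
    for taxon in taxa:
        parts = []
        for g, rows in zip(genes, per_gene):
            parts.append(rows.get(taxon, "?" * g.length))
        sequences[taxon] = "".join(parts)
    return Supermatrix(
        taxa=taxa,
        sequences=sequences,
        blocks=blocks,
        coding_in_frame={g.name: g.coding_in_frame for g in genes},
    )


def coverage_matrix(sm: Supermatrix):
    """Taxon × gene presence table plus per-taxon covered-gene counts.

    A cell is True iff the taxon's block holds at least one non-missing
    character (the per-taxon grey-bar display of the study).
    """
    data = {}
    for name, start, end in sm.blocks:
        col = []
        for taxon in sm.taxa:
            block = sm.sequences[taxon][start - 1 : end]
            col.append(any(ch not in MISSING_CHARS for ch in block))
        data[name] = col
    table = pd.DataFrame(data, index=sm.taxa)
    counts = table.sum(axis=1).astype(int)
    counts.name = "n_genes"
    return table, counts


def export_partitions(sm: Supermatrix, by_codon: bool = False) -> str:
    """Emit NEXUS-style charset lines for the gene blocks.

    With ``by_codon`` each gene yields three interleaved charsets
    (``start+offset - end\\3``); together they cover every column of the
    gene exactly once regardless of fragment length.  Genes not flagged
    coding-in-frame refuse codon partitioning.
    """
    lines = ["begin sets;"]
    for name, start, end in sm.blocks:
        if by_codon:
            if not sm.coding_in_frame.get(name, False):
                raise ConfigError(
                    f"gene {name!r} is not coding-in-frame; cannot "
                    "partition by codon position"
                )
            for offset in range(3):
                if start + offset > end:
                    continue
                lines.append(
                    f"    charset {name}_pos{offset + 1} = "
                    f"{start + offset}-{end}\\3;"
                )
        else:
            lines.append(f"    charset {name} = {start}-{end};")
    lines.append("end;")
    return "\n".join(lines) + "\n"


def charset_positions(sm: Supermatrix, by_codon: bool = False):
    """The exported charsets as explicit 1-based column lists (used to
    verify that charsets tile the matrix exactly once)."""
    out: dict[str, list[int]] = {}
    for name, start, end in sm.blocks:
        if by_codon:
            for offset in range(3):
                cols = list(range(start + offset, end + 1, 3))
                if cols:
                    out[f"{name}_pos{offset + 1}"] = cols
        else:
            out[name] = list(range(start, end + 1))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_gene_fasta(
    path, name: str | None = None, coding_in_frame: bool = True
) -> GeneAlignment:
    """Read one aligned gene from FASTA.

    Header convention: ``>taxon|source_id|EU`` — both extra fields are
    optional; a third field ``EU`` flags preferred-region origin.
    Spaces in taxon names may be written literally (the description is
    used, split on ``|``).
    """
    p = Path(path)
    records = []
    for rec in SeqIO.parse(str(p), "fasta"):
        fields = rec.description.split("|")
        taxon = fields[0].strip()
        source = fields[1].strip() if len(fields) > 1 else ""
        preferred = len(fields) > 2 and fields[2].strip().upper() == "EU"
        records.append(
            SequenceRecord(
                taxon=taxon,
                seq=str(rec.seq).upper(),
                preferred_origin=preferred,
                source_id=source,
            )
        )
    return GeneAlignment(
        name=name or p.stem, records=records, coding_in_frame=coding_in_frame
    )


def write_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for taxon in sm.taxa:
            fh.write(f">{taxon}\n{sm.sequences[taxon]}\n")


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: names of any length, two-space separator;
    spaces in names replaced by underscores (format limitation)."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for taxon in sm.taxa:
            fh.write(f"{taxon.replace(' ', '_')}  {sm.sequences[taxon]}\n")


def write_nexus(sm: Supermatrix, path, by_codon: bool = False) -> None:
    """NEXUS data block plus the sets block from :func:`export_partitions`."""
    def q(label: str) -> str:
        return f"'{label}'" if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>") else label

    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"    dimensions ntax={len(sm.taxa)} nchar={sm.length};\n")
        fh.write(
            '    format datatype=dna missing=? gap=-;\n    matrix\n'
        )
        for taxon in sm.taxa:
            fh.write(f"    {q(taxon)}  {sm.sequences[taxon]}\n")
        fh.write("    ;\nend;\n\n")
        fh.write(export_partitions(sm, by_codon=by_codon))


def read_nexus_matrix(path) -> Supermatrix:
    """Read back a NEXUS data block written by :func:`write_nexus`.

    Only the simple single-line-per-taxon layout this package writes is
    supported; charset lines are restored as blocks when present.
    """
    taxa: list[str] = []
    seqs: dict[str, str] = {}
    blocks: list[tuple[str, int, int]] = []
    in_matrix = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            low = line.lower()
            if low == "matrix":
                in_matrix = True
                continue
            if in_matrix:
                if line == ";":
                    in_matrix = False
                    continue
                if not line:
                    continue
                if line.startswith("'"):
                    endq = line.index("'", 1)
                    taxon = line[1:endq]
                    seq = line[endq + 1 :].strip()
                else:
                    taxon, seq = line.split(None, 1)
                taxa.append(taxon)
                seqs[taxon] = seq.strip()
            elif low.startswith("charset") and "\\" not in line:
                body = line[len("charset") :].strip().rstrip(";")
                name, rng = body.split("=")
                start, end = rng.strip().split("-")
                blocks.append((name.strip(), int(start), int(end)))
    if not taxa:
        raise ContractError(f"no data matrix found in {path}")
    if not blocks:
        blocks = [("all", 1, len(next(iter(seqs.values()))))]
    return Supermatrix(taxa=taxa, sequences=seqs, blocks=blocks)


def write_coverage_tsv(sm: Supermatrix, path) -> None:
    table, counts = coverage_matrix(sm)
    out = table.astype(int)
    out.insert(len(out.columns), "n_genes", counts)
    out.to_csv(path, sep="\t", index_label="taxon")
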