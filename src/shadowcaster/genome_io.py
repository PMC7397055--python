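"""Readers, writers and validation for the sequence and tabular inputs.

The unit of analysis is one in-frame CDS (:class:`GeneRecord`) carrying both
its nucleotide sequence and derived translation.  Proteomes of related
species and a five-column taxonomy table drive the phylogenetic stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

DNA_ALPHABET = frozenset("ACGTN")
# 20 canonical residues plus X for ambiguity.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

TAXONOMY_COLUMNS = ("species_id", "family", "order", "phylum", "superkingdom")


class SequenceError(ValueError):
    """Raised for malformed sequence input (frame, alphabet, duplicates)."""


def translate_cds(nt_seq: str, gene_id: str = "?") -> str:
    """Translate an in-frame CDS with the bacterial code (table 11).

    A single trailing stop codon is stripped; an internal stop is a hard
    error because both simulated and annotated CDS inputs are expected
    in-frame.  Codons containing N translate to X.
    """
    if len(nt_seq) < 3 or len(nt_seq) % 3 != 0:
        raise SequenceError(
            f"gene {gene_id!r}: CDS length {len(nt_seq)} is not a positive multiple of 3"
        )
    n_codons = len(nt_seq) // 3
    aa: list[str] = []
    for i in range(n_codons):
        codon = nt_seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise SequenceError(
                f"gene {gene_id!r}: internal stop codon {codon} at codon {i + 1}"
            )
        aa.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


@dataclass(frozen=True)
class GeneRecord:
    """One CDS of the recipient genome, with its translation."""

    gene_id: str
    nt_seq: str
    aa_seq: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.gene_id or re.search(r"\s", self.gene_id):
            raise SequenceError(f"invalid gene_id {self.gene_id!r}")
        nt = self.nt_seq.upper()
        if set(nt) - DNA_ALPHABET:
            bad = sorted(set(nt) - DNA_ALPHABET)
            raise SequenceError(f"gene {self.gene_id!r}: non-DNA characters {bad}")
        object.__setattr__(self, "nt_seq", nt)
        if not self.aa_seq:
            object.__setattr__(self, "aa_seq", translate_cds(nt, self.gene_id))


@dataclass(frozen=True)
class Proteome:
    """All protein sequences of one species."""

    species_id: str
    proteins: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.proteins]
        if len(set(ids)) != len(ids):
            raise SequenceError(f"proteome {self.species_id!r}: duplicate protein ids")
        for pid, seq in self.proteins:
            if not seq:
                raise SequenceError(f"protein {pid!r}: empty sequence")
            if set(seq) - AA_ALPHABET:
                bad = sorted(set(seq) - AA_ALPHABET)
                raise SequenceError(f"protein {pid!r}: non-amino-acid characters {bad}")

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.proteins]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.proteins]


@dataclass(frozen=True)
class TaxonomyRecord:
    """Rank labels of one species; any rank may be the sentinel ``NA``."""

    species_id: str
    family: str = "NA"
    order: str = "NA"
    phylum: str = "NA"
    superkingdom: str = "NA"


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Parse a nucleotide FASTA of in-frame CDS into :class:`GeneRecord` s.

    Records are uppercased; order is preserved.  Out-of-frame records,
    duplicate ids and internal stop codons are hard errors naming the gene.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GeneRecord(gene_id=rec.id, nt_seq=str(rec.seq)))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_cds_fasta(genes: Iterable[GeneRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.nt_seq), id=g.gene_id, description="") for g in genes]
    SeqIO.write(recs, str(path), "fasta")


def read_proteome_fasta(path: str | Path, species_id: str | None = None) -> Proteome:
    """Parse an amino-acid FASTA; species_id defaults to the file stem.

    Trailing ``*`` stop symbols are stripped; sequences are uppercased.
    """
    path = Path(path)
    proteins: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        proteins.append((rec.id, seq))
    if not proteins:
        raise SequenceError(f"no protein records in {path}")
    return Proteome(species_id=species_id or path.stem, proteins=tuple(proteins))


def write_proteome_fasta(proteome: Proteome, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.proteins]
    SeqIO.write(recs, str(path), "fasta")


def genes_to_proteome(genes: Sequence[GeneRecord], species_id: str) -> Proteome:
    """Derive a proteome from CDS records (ids carried over)."""
    return Proteome(
        species_id=species_id,
        proteins=tuple((g.gene_id, g.aa_seq) for g in genes),
    )


def read_taxonomy_table(path: str | Path) -> list[TaxonomyRecord]:
    """Read the 5-column taxonomy TSV; empty cells become ``NA``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise SequenceError(f"taxonomy table {path}: missing columns {sorted(missing)}")
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].iloc[0]
        raise SequenceError(f"taxonomy table {path}: duplicated species_id {dup!r}")
    out = []
    for row in df.itertuples(index=False):
        vals = {c: (getattr(row, c) or "NA") for c in TAXONOMY_COLUMNS}
        out.append(TaxonomyRecord(**vals))
    return out


def write_taxonomy_table(records: Iterable[TaxonomyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [[getattr(r, c) for c in TAXONOMY_COLUMNS] for r in records],
        columns=list(TAXONOMY_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
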