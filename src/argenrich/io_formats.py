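"""Readers and writers for the on-disk artifacts of the analysis.

All tabular artifacts are UTF-8, tab-separated files with a mandatory
header row; decimal point is ``.`` and scientific notation is accepted.
Protein sequences are plain FASTA.

The central conventions implemented here:

* absent quantification (``0`` or an empty cell) becomes an explicit
  missing value (NaN) on read — the downstream imputation model needs
  missing distinguished from measured zero;
* modified peptides may be encoded either inline, with parenthesized
  markers such as ``DTSLYRPALE(R)ELR`` attached to the residue
  immediately preceding the marker, or with per-modification-type
  offset columns; both encodings parse to identical records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

WT = "WT"
KO = "KO"
GENOTYPES = (WT, KO)

ROLE_INPUT = "input"
ROLE_ELUATE = "eluate"

MOD_TYPES = ("R", "R-me", "R-me2")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class DesignError(ValueError):
    """A sample design violated the experimental-layout constraints."""


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleLabel:
    """Identity of one quantified sample column."""

    genotype: str
    column_id: str
    role: str

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise DesignError(f"unknown genotype {self.genotype!r}")
        if self.role not in (ROLE_INPUT, ROLE_ELUATE):
            raise DesignError(f"unknown role {self.role!r}")


class SampleDesign:
    """Maps sample column names to :class:`SampleLabel` descriptions.

    Enforces the experimental layout: at most one eluate per
    (genotype, antibody column) and exactly one input per genotype.
    """

    def __init__(self, mapping: dict[str, SampleLabel]):
        seen_eluates: set[tuple[str, str]] = set()
        inputs: dict[str, str] = {}
        for name, label in mapping.items():
            if label.role == ROLE_ELUATE:
                key = (label.genotype, label.column_id)
                if key in seen_eluates:
                    raise DesignError(f"duplicate eluate sample for {key}")
                seen_eluates.add(key)
            else:
                if label.genotype in inputs:
                    raise DesignError(
                        f"more than one input sample for genotype {label.genotype}"
                    )
                inputs[label.genotype] = name
        for genotype in GENOTYPES:
            if genotype not in inputs:
                raise DesignError(f"missing input sample for genotype {genotype}")
        self.mapping = dict(mapping)
        self._inputs = inputs

    def __eq__(self, other):
        return isinstance(other, SampleDesign) and self.mapping == other.mapping

    def __len__(self):
        return len(self.mapping)

    @property
    def sample_names(self) -> list[str]:
        return list(self.mapping)

    def input_sample(self, genotype: str) -> str:
        return self._inputs[genotype]

    def eluate_samples(self, genotype: str) -> list[tuple[str, str]]:
        """(column_id, sample_name) pairs for a genotype, sorted by column."""
        pairs = [
            (label.column_id, name)
            for name, label in self.mapping.items()
            if label.role == ROLE_ELUATE and label.genotype == genotype
        ]
        return sorted(pairs)

    @property
    def column_ids(self) -> list[str]:
        return sorted({c for c, _ in self.eluate_samples(WT)})

    @classmethod
    def from_yaml(cls, path) -> "SampleDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mapping = {
            name: SampleLabel(spec["genotype"], str(spec.get("column_id", "")), spec["role"])
            for name, spec in raw.items()
        }
        return cls(mapping)

    def to_yaml(self, path) -> None:
        raw = {
            name: {
                "genotype": label.genotype,
                "column_id": label.column_id,
                "role": label.role,
            }
            for name, label in self.mapping.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# intensity table
# ---------------------------------------------------------------------------


@dataclass
class IntensityTable:
    """Protein x sample raw intensities with explicit missingness (NaN)."""

    protein_ids: list[str]
    gene_names: list[str]
    razor_unique: pd.DataFrame  # index protein_ids, columns WT/KO, int counts
    design: SampleDesign
    values: np.ndarray  # shape (n_proteins, n_samples), NaN = missing

    def __post_init__(self):
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise FormatError("duplicate protein accessions in table")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.design)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.design)} samples"
            )
        present = self.values[~np.isnan(self.values)]
        if present.size and present.min() <= 0:
            raise FormatError("present intensities must be > 0 (zeros become missing)")

    @property
    def samples(self) -> list[str]:
        return self.design.sample_names

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def subset(self, keep: np.ndarray) -> "IntensityTable":
        keep = np.asarray(keep)
        ids = [p for p, k in zip(self.protein_ids, keep) if k]
        genes = [g for g, k in zip(self.gene_names, keep) if k]
        return IntensityTable(
            protein_ids=ids,
            gene_names=genes,
            razor_unique=self.razor_unique.loc[ids],
            design=self.design,
            values=self.values[keep],
        )


def read_protein_groups(path, design: SampleDesign) -> IntensityTable:
    """Read a protein-group quantification TSV into an :class:`IntensityTable`.

    Required columns: ``protein_id``, ``gene_names``, ``razor_unique_WT``,
    ``razor_unique_KO`` and one intensity column per sample in *design*.
    ``0`` and empty intensity cells become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "gene_names", "razor_unique_WT", "razor_unique_KO"]
    required += design.sample_names
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    ids = df["protein_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = df["protein_id"][df["protein_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate accession {dup!r} in {path}")
    genes = df["gene_names"].fillna("").tolist()
    razor = pd.DataFrame(
        {g: df[f"razor_unique_{g}"].astype(int).to_numpy() for g in GENOTYPES},
        index=ids,
    )
    n = len(ids)
    values = np.full((n, len(design)), np.nan)
    n_zeroed = 0
    for j, name in enumerate(design.sample_names):
        col = df[name]
        for i, cell in enumerate(col):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric intensity {cell!r} in column {name!r}, row {i + 2} of {path}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"negative intensity {v} in column {name!r}, row {i + 2} of {path}"
                )
            if v == 0:
                n_zeroed += 1
                continue
            values[i, j] = v
    if n_zeroed:
        logger.info("read_protein_groups: converted %d zero intensities to missing", n_zeroed)
    return IntensityTable(ids, genes, razor, design, values)


def write_protein_groups(table: IntensityTable, path) -> None:
    out = pd.DataFrame({"protein_id": table.protein_ids, "gene_names": table.gene_names})
    for g in GENOTYPES:
        out[f"razor_unique_{g}"] = table.razor_unique[g].to_numpy()
    for j, name in enumerate(table.samples):
        col = table.values[:, j]
        out[name] = ["" if np.isnan(v) else repr(float(v)) for v in col]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide evidence / site tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mod:
    """One modification on a peptide: 1-based offset, residue, type."""

    offset: int
    residue: str
    mod_type: str


@dataclass(frozen=True)
class PeptideEvidence:
    """One modified-peptide evidence row."""

    peptide_seq: str
    leading_protein: str
    mods: tuple[Mod, ...]
    localization_probability: float
    pep: float
    genotype: str = WT
    column_id: str = "c1"
    gene: str = ""

    def __post_init__(self):
        if not re.fullmatch(f"[{AMINO_ACIDS}]+", self.peptide_seq):
            raise FormatError(f"peptide {self.peptide_seq!r} is not a plain AA string")
        for m in self.mods:
            if not 1 <= m.offset <= len(self.peptide_seq):
                raise FormatError(
                    f"mod offset {m.offset} outside peptide {self.peptide_seq!r}"
                )
            if self.peptide_seq[m.offset - 1] != m.residue:
                raise FormatError(
                    f"mod residue {m.residue!r} does not match peptide position "
                    f"{m.offset} ({self.peptide_seq[m.offset - 1]!r})"
                )
            if m.residue not in ("E", "D") and m.offset != 1:
                raise FormatError(
                    f"modified residue {m.residue!r} at offset {m.offset} is neither "
                    "E/D nor the peptide N terminus"
                )
            if m.mod_type not in MOD_TYPES:
                raise FormatError(f"unknown mod type {m.mod_type!r}")
        if not 0 <= self.localization_probability <= 1:
            raise FormatError("localization probability outside [0, 1]")
        if not 0 <= self.pep <= 1:
            raise FormatError("PEP outside [0, 1]")
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype {self.genotype!r}")

    @property
    def first_gene(self) -> str:
        """First-listed gene symbol (canonical symbol for counting)."""
        g = self.gene or self.leading_protein
        return g.split(";")[0].strip()


_MARKER_RE = re.compile(r"\(([^)]*)\)")


def parse_inline_peptide(marked: str) -> tuple[str, tuple[Mod, ...]]:
    """Parse a parenthesized peptide string into (bare sequence, mods).

    A marker like ``(R)``, ``(R-me)`` or ``(R-me2)`` attaches to the
    residue immediately preceding the parenthesis; offsets are 1-based
    in the bare (marker-free) sequence.
    """
    bare: list[str] = []
    mods: list[Mod] = []
    pos = 0
    while pos < len(marked):
        ch = marked[pos]
        if ch == "(":
            m = _MARKER_RE.match(marked, pos)
            if m is None:
                raise FormatError(f"unterminated marker in {marked!r}")
            mod_type = m.group(1)
            if mod_type not in MOD_TYPES:
                raise FormatError(f"unknown marker {mod_type!r} in {marked!r}")
            if not bare:
                raise FormatError(f"marker not preceded by a residue in {marked!r}")
            mods.append(Mod(len(bare), bare[-1], mod_type))
            pos = m.end()
        else:
            bare.append(ch.upper())
            pos += 1
    return "".join(bare), tuple(mods)


def format_inline_peptide(peptide_seq: str, mods: tuple[Mod, ...]) -> str:
    """Inverse of :func:`parse_inline_peptide`."""
    out = []
    by_offset = {m.offset: m for m in mods}
    for i, ch in enumerate(peptide_seq, start=1):
        out.append(ch)
        if i in by_offset:
            out.append(f"({by_offset[i].mod_type})")
    return "".join(out)


_SITE_COLUMN_ALIASES = {
    "localization_probability": "localization_probability",
    "localization_prob": "localization_probability",
    "pep": "pep",
    "peptide": "peptide",
    "leading_protein": "leading_protein",
    "protein_id": "leading_protein",
    "gene_names": "gene_names",
    "gene": "gene_names",
    "genotype": "genotype",
    "column_id": "column_id",
    "r_offsets": "r_offsets",
    "r_me_offsets": "r_me_offsets",
    "r_me2_offsets": "r_me2_offsets",
}

_OFFSET_COLUMNS = (("r_offsets", "R"), ("r_me_offsets", "R-me"), ("r_me2_offsets", "R-me2"))


def read_site_table(path) -> list[PeptideEvidence]:
    """Read a modified-peptide evidence TSV.

    Modifications come either from inline parenthesized markers in the
    ``peptide`` column or, when the peptide is unmarked, from the
    per-type 1-based offset columns ``r_offsets`` / ``r_me_offsets`` /
    ``r_me2_offsets`` (comma-separated). Both encodings yield identical
    records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [
        _SITE_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns
    ]
    if "peptide" not in df.columns:
        raise FormatError(f"missing required column 'peptide' in {path}")
    records: list[PeptideEvidence] = []
    for _, row in df.iterrows():
        marked = str(row["peptide"]).strip()
        if "(" in marked:
            seq, mods = parse_inline_peptide(marked)
        else:
            seq = marked.upper()
            mods_list: list[Mod] = []
            for colname, mod_type in _OFFSET_COLUMNS:
                cell = row.get(colname)
                if cell is None or pd.isna(cell) or str(cell).strip() == "":
                    continue
                for tok in str(cell).split(","):
                    off = int(tok.strip())
                    if not 1 <= off <= len(seq):
                        raise FormatError(f"offset {off} outside peptide {seq!r}")
                    mods_list.append(Mod(off, seq[off - 1], mod_type))
            mods = tuple(sorted(mods_list, key=lambda m: m.offset))
        gene = "" if pd.isna(row.get("gene_names")) else str(row.get("gene_names", "")).strip()
        protein = row.get("leading_protein")
        if protein is None or pd.isna(protein) or str(protein).strip() == "":
            protein = gene.split(";")[0].strip()
        genotype = row.get("genotype")
        genotype = WT if genotype is None or pd.isna(genotype) else str(genotype).strip()
        column_id = row.get("column_id")
        column_id = "c1" if column_id is None or pd.isna(column_id) else str(column_id).strip()
        records.append(
            PeptideEvidence(
                peptide_seq=seq,
                leading_protein=str(protein).strip(),
                mods=mods,
                localization_probability=float(row["localization_probability"]),
                pep=float(row["pep"]),
                genotype=genotype,
                column_id=column_id,
                gene=gene,
            )
        )
    return records


def write_site_table(records: list[PeptideEvidence], path, inline: bool = True) -> None:
    """Write evidence rows; ``inline`` selects the marker encoding."""
    rows = []
    for r in records:
        row = {
            "leading_protein": r.leading_protein,
            "gene_names": r.gene,
            "genotype": r.genotype,
            "column_id": r.column_id,
            "localization_probability": repr(r.localization_probability),
            "pep": repr(r.pep),
        }
        if inline:
            row["peptide"] = format_inline_peptide(r.peptide_seq, r.mods)
        else:
            row["peptide"] = r.peptide_seq
            for colname, mod_type in _OFFSET_COLUMNS:
                row[colname] = ",".join(
                    str(m.offset) for m in r.mods if m.mod_type == mod_type
                )
        rows.append(row)
    cols = ["leading_protein", "gene_names", "peptide"]
    if not inline:
        cols += [c for c, _ in _OFFSET_COLUMNS]
    cols += ["localization_probability", "pep", "genotype", "column_id"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _fasta_accession(header_id: str) -> str:
    # UniProt "sp|ACC|NAME" / "tr|ACC|NAME" headers yield ACC; else the
    # first whitespace-delimited token as-is.
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_id


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an accession -> sequence mapping."""
    db: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _fasta_accession(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"empty sequence for {acc!r} in {path}")
        if acc in db:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        db[acc] = seq
    if not db:
        raise FormatError(f"no sequences in {path}")
    return db


def write_fasta(db: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in db.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    score: float


def read_edge_list(path) -> list[Edge]:
    """Read a weighted undirected edge list (node_a, node_b, score).

    Self-edges are dropped; a duplicate unordered pair is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str},
                     float_precision="round_trip")
    for col in ("node_a", "node_b", "score"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    edges: list[Edge] = []
    seen: set[frozenset] = set()
    n_self = 0
    for _, row in df.iterrows():
        a, b, s = str(row["node_a"]), str(row["node_b"]), float(row["score"])
        if not 0 <= s <= 1:
            raise FormatError(f"edge score {s} outside [0, 1] in {path}")
        if a == b:
            n_self += 1
            continue
        key = frozenset((a, b))
        if key in seen:
            raise FormatError(f"duplicate unordered pair ({a}, {b}) in {path}")
        seen.add(key)
        edges.append(Edge(a, b, s))
    if n_self:
        logger.info("read_edge_list: dropped %d self-edges", n_self)
    return edges


def write_edge_list(edges: list[Edge], path) -> None:
    pd.DataFrame(
        [{"node_a": e.node_a, "node_b": e.node_b, "score": repr(e.score)} for e in edges],
        columns=["node_a", "node_b", "score"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def read_enriched_table(path) -> pd.DataFrame:
    """Read a per-protein results table (gene, fold change, p value).

    This reader accepts both the pipeline's own output and transcribed
    published tables; only gene/fold-change/p columns are required.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"fold change": "fold_change", "p": "p_value", "avg_fold_change": "fold_change"}
    df = df.rename(columns=rename)
    for col in ("gene_names", "fold_change", "p_value"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    df["fold_change"] = df["fold_change"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    return df


def write_results(records, path) -> None:
    """Write :class:`~argenrich.enrichment.EnrichmentRecord` rows to TSV."""
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "gene_names": r.gene,
        }
        for cid, lfc in zip(r.column_ids, r.per_column_log2fc):
            row[f"log2fc_{cid}"] = repr(float(lfc))
        row.update(
            {
                "avg_fold_change": repr(float(r.avg_fold_change)),
                "p_value": repr(float(r.p_value)),
                "q_value": repr(float(r.q_value)),
                "n_wt_detected": r.n_wt_detected,
                "passes_qc": r.passes_qc,
                "enriched": r.enriched,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results(path):
    """Round-trip reader for :func:`write_results`."""
    from .enrichment import EnrichmentRecord

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str}, float_precision="round_trip")
    lfc_cols = [c for c in df.columns if c.startswith("log2fc_")]
    column_ids = tuple(c[len("log2fc_") :] for c in lfc_cols)
    records = []
    for _, row in df.iterrows():
        records.append(
            EnrichmentRecord(
                protein_id=str(row["protein_id"]),
                gene="" if pd.isna(row["gene_names"]) else str(row["gene_names"]),
                column_ids=column_ids,
                per_column_log2fc=tuple(float(row[c]) for c in lfc_cols),
                avg_fold_change=float(row["avg_fold_change"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                n_wt_detected=int(row["n_wt_detected"]),
                passes_qc=bool(row["passes_qc"]),
                enriched=bool(row["enriched"]),
            )
        )
    return records
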