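"""Mapping and confidence classification of arginylation sites.

Peptide-level evidence is mapped onto protein coordinates, sites whose
first peptide residue directly follows an Arg in the protein are removed
(missed-cleavage artifacts), and the remainder is tiered by knockout
exclusivity, localization probability and posterior error probability:

* ``nonspecific`` — observed in any knockout sample;
* ``high``       — wildtype-exclusive, localization > 0.75, PEP <= 0.01;
* ``medium``     — wildtype-exclusive otherwise;
* ``removed``    — preceded-by-Arg peptide-start artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .io_formats import KO, WT, Mod, PeptideEvidence

logger = logging.getLogger(__name__)

LOC_THRESHOLD = 0.75
PEP_THRESHOLD = 0.01

CONF_HIGH = "high"
CONF_MEDIUM = "medium"
CONF_REMOVED = "removed"
CONF_NONSPECIFIC = "nonspecific"
CONFIDENCE_TIERS = (CONF_HIGH, CONF_MEDIUM, CONF_REMOVED, CONF_NONSPECIFIC)


@dataclass(frozen=True)
class ProteinMod:
    """One modified residue in protein coordinates (1-based)."""

    position: int | None  # None when no sequence database was supplied
    residue: str
    mod_type: str
    peptide_offset: int = 0  # 1-based offset in the evidence peptide


@dataclass
class ArgSite:
    """One (merged) arginylation site record.

    A record corresponds to one evidence row's set of modified residues
    (``site_granularity="row"``) or to a single residue
    (``site_granularity="residue"``). ``residue`` / ``position_in_protein``
    expose the first modified residue.
    """

    protein_id: str
    gene: str
    mods: tuple[ProteinMod, ...]
    peptide_seq: str
    localization_probability: float
    pep: float
    genotypes_observed: frozenset
    preceded_by_arg_at_peptide_start: bool
    peptide_start: int | None = None
    ambiguous_mapping: bool = False
    confidence: str = ""

    @property
    def residue(self) -> str:
        return self.mods[0].residue

    @property
    def position_in_protein(self) -> int | None:
        return self.mods[0].position

    @property
    def first_gene(self) -> str:
        g = self.gene or self.protein_id
        return g.split(";")[0].strip()

    def positions_key(self) -> tuple:
        """Stable sort key over the modified positions."""
        return tuple(
            (m.position if m.position is not None else m.peptide_offset, m.mod_type)
            for m in self.mods
        )

    @property
    def side_chain(self) -> bool:
        """True when every modified residue is an E/D side chain."""
        return all(m.residue in ("E", "D") for m in self.mods)


@dataclass(frozen=True)
class UnmappedEvidence:
    """Evidence whose peptide was not found in its leading protein."""

    evidence: PeptideEvidence
    reason: str


def map_sites(
    evidence: list[PeptideEvidence],
    db: dict[str, str] | None,
    site_granularity: str = "row",
) -> tuple[list[ArgSite], list[UnmappedEvidence]]:
    """Map peptide evidence onto protein coordinates and merge replicates.

    Evidence rows for the same (protein, modified positions, types) are
    merged keeping the best (highest) localization probability and lowest
    PEP, with genotypes unioned. With ``db=None`` positions stay in
    peptide coordinates (``position=None``) and the preceded-by-Arg flag
    is always False; this is how published site tables, which carry no
    sequence database, are classified.

    Returns (sites, unmapped-evidence warnings).
    """
    if site_granularity not in ("row", "residue"):
        raise ValueError(f"unknown site_granularity {site_granularity!r}")
    unmapped: list[UnmappedEvidence] = []
    merged: dict[tuple, dict] = {}
    for ev in evidence:
        if not ev.mods:
            continue
        start = None
        ambiguous = False
        preceded = False
        if db is not None:
            seq = db.get(ev.leading_protein)
            if seq is None:
                unmapped.append(UnmappedEvidence(ev, "leading protein not in database"))
                continue
            start = seq.find(ev.peptide_seq)
            if start == -1:
                unmapped.append(UnmappedEvidence(ev, "peptide not found in protein"))
                continue
            start += 1  # 1-based protein position of the peptide start
            if seq.find(ev.peptide_seq, start) != -1:
                ambiguous = True
                logger.warning(
                    "peptide %s occurs more than once in %s; first match used",
                    ev.peptide_seq,
                    ev.leading_protein,
                )
            preceded = (
                any(m.offset == 1 for m in ev.mods)
                and start > 1
                and seq[start - 2] == "R"
            )
        if db is not None:
            pmods = tuple(
                ProteinMod(start + m.offset - 1, m.residue, m.mod_type, m.offset)
                for m in ev.mods
            )
        else:
            pmods = tuple(ProteinMod(None, m.residue, m.mod_type, m.offset) for m in ev.mods)
        if site_granularity == "row":
            groups = [pmods]
        else:
            groups = [(m,) for m in pmods]
        for group in groups:
            if db is not None:
                # merge across peptides covering the same protein position(s)
                key = (
                    ev.leading_protein,
                    tuple(sorted((m.position, m.mod_type) for m in group)),
                )
            else:
                key = (
                    ev.leading_protein,
                    ev.peptide_seq,
                    tuple(sorted((m.peptide_offset, m.mod_type) for m in group)),
                )
            entry = merged.get(key)
            if entry is None:
                merged[key] = {
                    "protein_id": ev.leading_protein,
                    "gene": ev.gene,
                    "mods": group,
                    "peptide_seq": ev.peptide_seq,
                    "loc": ev.localization_probability,
                    "pep": ev.pep,
                    "genotypes": {ev.genotype},
                    "preceded": preceded,
                    "start": start,
                    "ambiguous": ambiguous,
                }
            else:
                entry["loc"] = max(entry["loc"], ev.localization_probability)
                entry["pep"] = min(entry["pep"], ev.pep)
                entry["genotypes"].add(ev.genotype)
                entry["preceded"] = entry["preceded"] or preceded
                entry["ambiguous"] = entry["ambiguous"] or ambiguous
    sites = [
        ArgSite(
            protein_id=e["protein_id"],
            gene=e["gene"],
            mods=e["mods"],
            peptide_seq=e["peptide_seq"],
            localization_probability=e["loc"],
            pep=e["pep"],
            genotypes_observed=frozenset(e["genotypes"]),
            preceded_by_arg_at_peptide_start=e["preceded"],
            peptide_start=e["start"],
            ambiguous_mapping=e["ambiguous"],
        )
        for e in merged.values()
    ]
    if db is not None:
        for s in sites:
            seq = db[s.protein_id]
            for m in s.mods:
                assert seq[m.position - 1] == m.residue, "coordinate consistency violated"
    return sites, unmapped


def apply_preceding_arg_filter(
    sites: list[ArgSite], keep: set[tuple[str, int]] = frozenset()
) -> list[ArgSite]:
    """Mark preceded-by-Arg peptide-start sites as removed.

    ``keep`` lists (protein_id, position) overrides that are exempted.
    """
    out = []
    n_removed = 0
    for s in sites:
        if s.preceded_by_arg_at_peptide_start and (s.protein_id, s.position_in_protein) not in keep:
            out.append(replace(s, confidence=CONF_REMOVED))
            n_removed += 1
        else:
            out.append(s)
    if n_removed:
        logger.info(
            "preceding-Arg filter: removed %d / %d sites (peptide-start residue "
            "directly preceded by Arg)",
            n_removed,
            len(sites),
        )
    return out


def classify_confidence(
    sites: list[ArgSite],
    loc_threshold: float = LOC_THRESHOLD,
    pep_threshold: float = PEP_THRESHOLD,
) -> list[ArgSite]:
    """Assign a confidence tier to every not-yet-removed site."""
    out = []
    for s in sites:
        if s.confidence == CONF_REMOVED:
            out.append(s)
            continue
        if KO in s.genotypes_observed:
            conf = CONF_NONSPECIFIC
        elif (
            s.localization_probability > loc_threshold
            and s.pep <= pep_threshold
            and s.side_chain  # N-terminal non-E/D mods never tier high
        ):
            conf = CONF_HIGH
        else:
            conf = CONF_MEDIUM
        out.append(replace(s, confidence=conf))
    return out


def summarize_sites(sites: list[ArgSite]) -> dict[str, dict[str, int]]:
    """Per-tier counts of site records and distinct first-listed genes."""
    summary = {tier: {"n_sites": 0, "genes": set()} for tier in CONFIDENCE_TIERS}
    for s in sites:
        if s.confidence not in summary:
            raise ValueError(f"site without classified confidence: {s!r}")
        summary[s.confidence]["n_sites"] += 1
        summary[s.confidence]["genes"].add(s.first_gene)
    return {
        tier: {"n_sites": d["n_sites"], "n_proteins": len(d["genes"])}
        for tier, d in summary.items()
    }


def sites_to_frame(sites: list[ArgSite]) -> pd.DataFrame:
    """Flatten site records for TSV output."""
    rows = []
    for s in sites:
        rows.append(
            {
                "protein_id": s.protein_id,
                "gene_names": s.gene,
                "positions": ";".join(
                    f"{m.residue}{m.position if m.position is not None else '?'}"
                    for m in s.mods
                ),
                "mod_types": ";".join(m.mod_type for m in s.mods),
                "peptide": s.peptide_seq,
                "localization_probability": repr(s.localization_probability),
                "pep": repr(s.pep),
                "genotypes_observed": ";".join(sorted(s.genotypes_observed)),
                "preceded_by_arg_at_peptide_start": s.preceded_by_arg_at_peptide_start,
                "ambiguous_mapping": s.ambiguous_mapping,
                "confidence": s.confidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "gene_names",
            "positions",
            "mod_types",
            "peptide",
            "localization_probability",
            "pep",
            "genotypes_observed",
            "preceded_by_arg_at_peptide_start",
            "ambiguous_mapping",
            "confidence",
        ],
    )
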