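"""Readers and writers for the pipeline's external tables and sequences.

All tabular inputs are tab-delimited UTF-8 with a header row; missing
intensities are written as ``NA`` and held in memory as ``numpy.nan``.
A recorded intensity of 0 is treated as missing on load (the usual
label-free convention: zero means "not observed", and it would otherwise
poison the ratio arithmetic downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: the 20 standard amino acids
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: annotation namespaces the pipeline understands
NAMESPACES = ("GO-BP", "GO-CC", "GO-MF", "KEGG", "DOMAIN", "COMPARTMENT")

#: ambiguity codes retained on FASTA load but flagged in the log
AMBIGUOUS_RESIDUES = set("UBZXO")

SITE_COLUMNS = ("protein_id", "position", "residue", "localization_prob")


class FormatError(ValueError):
    """Raised when an input file violates the documented contract."""


def make_site_id(protein_id: str, residue: str, position: int) -> str:
    """Canonical site identifier, e.g. ``E3N88_00970_K65``."""
    return f"{protein_id}_{residue}{position}"


@dataclass
class SiteIntensityTable:
    """Per-site raw intensities across samples.

    Attributes
    ----------
    sites
        One row per modification site, indexed by ``site_id``, with columns
        ``protein_id``, ``position`` (1-based), ``residue`` and
        ``localization_prob``.
    intensities
        ``site_id`` x ``sample_id`` matrix of positive intensities with
        ``nan`` for missing cells.
    sample_groups
        Mapping ``sample_id`` -> group label (e.g. ``C`` / ``SA``).
    """

    sites: pd.DataFrame
    intensities: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups.get(s) == group]

    def validate(self) -> None:
        if not self.sites.index.is_unique:
            dups = self.sites.index[self.sites.index.duplicated()].unique()
            raise FormatError(f"duplicate site_id: {', '.join(dups)}")
        bad_pos = self.sites["position"] < 1
        if bad_pos.any():
            raise FormatError(
                f"positions must be >= 1; offending sites: "
                f"{', '.join(self.sites.index[bad_pos])}"
            )
        bad_res = ~self.sites["residue"].isin(list(AA_ALPHABET))
        if bad_res.any():
            raise FormatError(
                f"residue outside the 20-letter alphabet: "
                f"{', '.join(self.sites.index[bad_res])}"
            )
        probs = self.sites["localization_prob"]
        if ((probs < 0) | (probs > 1)).any():
            raise FormatError("localization_prob must lie in [0, 1]")
        if (self.intensities.to_numpy() < 0).any():
            raise FormatError("negative intensity encountered")
        unknown = [s for s in self.samples if s not in self.sample_groups]
        if unknown:
            raise FormatError(f"samples without group assignment: {unknown}")


@dataclass
class ProteinQuantTable:
    """Protein-level intensities over the same sample universe."""

    intensities: pd.DataFrame  # protein_id x sample_id, nan = missing

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)


def read_site_table(path: str | Path, group_map: dict[str, str]) -> SiteIntensityTable:
    """Load a modification-site intensity table.

    Columns: ``protein_id``, ``position``, ``residue``,
    ``localization_prob``, then one column per sample. Zeros become
    missing; duplicate site ids and negative intensities are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing_cols = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s): {missing_cols}")
    sample_cols = [c for c in df.columns if c not in SITE_COLUMNS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample intensity columns found")

    df["position"] = df["position"].astype(int)
    site_ids = [
        make_site_id(p, r, pos)
        for p, r, pos in zip(df["protein_id"], df["residue"], df["position"])
    ]
    dup = pd.Index(site_ids)[pd.Index(site_ids).duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate site_id: {', '.join(dup)}")
    df.index = pd.Index(site_ids, name="site_id")

    inten = df[sample_cols].astype(float)
    neg = np.where(inten.to_numpy() < 0)
    if len(neg[0]):
        row = int(neg[0][0])
        raise FormatError(f"{path}: negative intensity at data row {row + 1}")
    n_zero = int((inten == 0).sum().sum())
    inten = inten.replace(0.0, np.nan)
    table = SiteIntensityTable(
        sites=df[list(SITE_COLUMNS)],
        intensities=inten,
        sample_groups=dict(group_map),
    )
    table.validate()
    log.info(
        "read %d sites x %d samples from %s (%d zero cells set to missing)",
        len(df), len(sample_cols), path, n_zero,
    )
    return table


def write_site_table(table: SiteIntensityTable, path: str | Path) -> None:
    out = pd.concat([table.sites, table.intensities], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_protein_table(path: str | Path) -> ProteinQuantTable:
    """Load protein-level intensities: ``protein_id`` then sample columns."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'protein_id'")
    if df["protein_id"].duplicated().any():
        dups = df.loc[df["protein_id"].duplicated(), "protein_id"].unique()
        raise FormatError(f"{path}: duplicate protein_id: {', '.join(dups)}")
    df = df.set_index("protein_id")
    inten = df.astype(float)
    if (inten.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative intensity in protein table")
    inten = inten.replace(0.0, np.nan)
    return ProteinQuantTable(intensities=inten)


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    table.intensities.to_csv(
        path, sep="\t", index=True, na_rep="NA", float_format="%.10g"
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; ID = first whitespace token of the header.

    Sequences are uppercased; ambiguity codes are kept but flagged.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        odd = sorted(set(seq) & AMBIGUOUS_RESIDUES)
        if odd:
            log.warning("sequence %s contains ambiguity codes %s", rec.id, odd)
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"{path}: empty FASTA file")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Load protein -> term annotations.

    Columns: ``protein_id``, ``namespace``, ``term_id``, ``term_name``.
    Exact duplicate (protein, namespace, term) rows are dropped; an
    unknown namespace is fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "namespace", "term_id", "term_name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    bad = sorted(set(df["namespace"]) - set(NAMESPACES))
    if bad:
        raise FormatError(
            f"{path}: unknown namespace(s) {bad}; expected one of {list(NAMESPACES)}"
        )
    before = len(df)
    df = df.drop_duplicates(subset=["protein_id", "namespace", "term_id"])
    if len(df) < before:
        log.info("dropped %d duplicate annotation rows", before - len(df))
    return df.reset_index(drop=True)


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Load an undirected interaction edge table.

    Columns: ``protein_a``, ``protein_b``, ``score`` in [0, 1]. Self-loops
    are dropped (with a warning count); (a, b) and (b, a) collapse to one
    edge keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    required = ["protein_a", "protein_b", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    df["score"] = df["score"].astype(float)
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise FormatError(f"{path}: edge scores must lie in [0, 1]")
    return normalize_edges(df)


def normalize_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops, orient edges canonically and dedup keeping max score."""
    loops = df["protein_a"] == df["protein_b"]
    if loops.any():
        log.warning("dropped %d self-loop edge(s)", int(loops.sum()))
    df = df.loc[~loops].copy()
    a = df[["protein_a", "protein_b"]].min(axis=1)
    b = df[["protein_a", "protein_b"]].max(axis=1)
    df["protein_a"], df["protein_b"] = a, b
    df = (
        df.groupby(["protein_a", "protein_b"], as_index=False)["score"]
        .max()
        .sort_values(["protein_a", "protein_b"])
        .reset_index(drop=True)
    )
    return df


def write_edge_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
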