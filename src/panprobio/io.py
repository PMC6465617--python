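"""Readers and writers for the plain-text formats the pipeline consumes."""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO

from .complementarity import KOProfile, ModuleDefinition

__all__ = [
    "read_fasta",
    "read_fasta_dir",
    "write_fasta",
    "read_metadata",
    "read_hits",
    "read_ko_profiles",
    "read_module_definitions",
]


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} (order-independent dict)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_fasta_dir(directory, suffixes=(".fa", ".fasta", ".faa", ".fna")
                   ) -> dict[str, dict[str, str]]:
    """Directory of per-genome FASTA files -> {stem: {id: seq}}."""
    out = {}
    for name in sorted(os.listdir(directory)):
        stem, ext = os.path.splitext(name)
        if ext.lower() in suffixes:
            out[stem] = read_fasta(os.path.join(directory, name))
    if not out:
        raise FileNotFoundError(f"no FASTA files in {directory}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")


def read_metadata(path) -> pd.DataFrame:
    """Genome metadata TSV with at least genome_id and species_label."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    for col in ("genome_id", "species_label"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing column {col!r}")
    return df


def read_hits(path) -> pd.DataFrame:
    """BLAST-outfmt-6-like hit TSV plus database (and optional ARDB
    per-gene identity threshold) columns."""
    return pd.read_csv(path, sep="\t")


def read_ko_profiles(path, species_of: dict[str, str] | None = None
                     ) -> dict[str, KOProfile]:
    """KO assignment TSV (genome_id, KO; one row per assignment) ->
    per-genome profiles. ``species_of`` supplies species labels (defaults to
    the genome id itself)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "KO"} <= set(df.columns):
        raise ValueError("KO table needs columns genome_id and KO")
    profiles = {}
    for gid, sub in df.groupby("genome_id"):
        species = species_of.get(gid, gid) if species_of else gid
        profiles[gid] = KOProfile(gid, species, set(sub["KO"]))
    return profiles


def read_module_definitions(path) -> list[ModuleDefinition]:
    """Module definition TSV (module_id, KO; one row per required KO)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"module_id", "KO"} <= set(df.columns):
        raise ValueError("module table needs columns module_id and KO")
    return [ModuleDefinition(mid, frozenset(sub["KO"]))
            for mid, sub in df.groupby("module_id")]
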