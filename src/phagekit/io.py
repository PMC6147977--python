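"""Readers and writers for the pipeline's plain-text formats.

Plate-reader CSV (columns strain, moi, antibiotic, conc_mg_l, replicate,
time_h, od590), FASTA proteomes (headers ``genome|gene`` or
``genome|gene|family`` when truth labels are carried), family-matrix and
distance-matrix TSV, Newick, YAML configuration. All files are UTF-8; CSV
uses comma and ".", no thousands separators. Writers round-trip losslessly
through their readers.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phagekit.datatypes import ODTimeSeries, Treatment
from phagekit.pangenome import GeneFamilyMatrix, PhageGenomeSet
from phagekit.phylo import DistanceMatrix

__all__ = [
    "write_plate_csv",
    "read_plate_csv",
    "write_proteome_fasta",
    "read_proteome_fastas",
    "write_family_matrix",
    "read_family_matrix",
    "write_distance_matrix",
    "read_distance_matrix",
    "load_config",
    "derive_seed",
    "rng_for_stage",
]

PLATE_COLUMNS = ["strain", "moi", "antibiotic", "conc_mg_l", "replicate",
                 "time_h", "od590"]


# ---------------------------------------------------------------------------
# plate-reader CSV
# ---------------------------------------------------------------------------

def write_plate_csv(series: list[ODTimeSeries], path) -> None:
    rows = []
    for s in series:
        t = s.treatment
        for time, od in zip(s.times, s.od):
            rows.append(
                (t.strain_id, t.moi, t.antibiotic or "none",
                 t.concentration, s.replicate, time, od)
            )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_csv(path) -> list[ODTimeSeries]:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plate CSV columns {missing}")
    out: list[ODTimeSeries] = []
    keys = ["strain", "moi", "antibiotic", "conc_mg_l", "replicate"]
    for key, grp in df.groupby(keys, sort=False):
        strain, moi, antibiotic, conc, rep = key
        antibiotic = None if str(antibiotic) == "none" else str(antibiotic)
        grp = grp.sort_values("time_h")
        try:
            out.append(
                ODTimeSeries(
                    treatment=Treatment(
                        strain_id=str(strain), moi=float(moi),
                        antibiotic=antibiotic, concentration=float(conc),
                    ),
                    replicate=int(rep),
                    times=grp["time_h"].to_numpy(),
                    od=grp["od590"].to_numpy(),
                )
            )
        except ValueError as exc:
            raise ValueError(
                f"{path}: invalid series for arm {key}: {exc}"
            ) from exc
    return out


# ---------------------------------------------------------------------------
# FASTA proteomes
# ---------------------------------------------------------------------------

def write_proteome_fasta(genomes: PhageGenomeSet, directory) -> list[Path]:
    """One FASTA per genome; headers ``genome|gene`` plus ``|family`` when
    the set carries truth labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome_id, genes in genomes.genomes.items():
        records = []
        for gene_id, seq in genes:
            header = f"{genome_id}|{gene_id}"
            if genomes.truth and header in genomes.truth:
                header += f"|{genomes.truth[header]}"
            records.append(
                SeqRecord(Seq(seq), id=header, description="")
            )
        path = directory / f"{genome_id}.faa"
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    return paths


def read_proteome_fastas(paths) -> PhageGenomeSet:
    """Read one-FASTA-per-genome proteomes.

    The genome id comes from the ``genome|gene`` header prefix when present,
    else from the file stem. Truth family labels are picked up from a third
    ``|``-separated header field when every record carries one.
    """
    genomes: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, str] = {}
    n_genes = 0
    for path in map(Path, paths):
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) >= 2:
                genome_id, gene_id = parts[0], parts[1]
            else:
                genome_id, gene_id = path.stem, parts[0]
            if len(parts) >= 3:
                truth[f"{genome_id}|{gene_id}"] = parts[2]
            genomes.setdefault(genome_id, []).append((gene_id, str(rec.seq)))
            n_genes += 1
    if n_genes == 0:
        raise ValueError(f"no FASTA records found in {list(map(str, paths))}")
    return PhageGenomeSet(genomes=genomes, truth=truth or None)


# ---------------------------------------------------------------------------
# matrices as TSV
# ---------------------------------------------------------------------------

def write_family_matrix(matrix: GeneFamilyMatrix, path, membership_path=None) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="family")
    if membership_path is not None:
        with open(membership_path, "w") as fh:
            fh.write("family\tgene\n")
            for fam in matrix.families:
                for qid in matrix.membership.get(fam, []):
                    fh.write(f"{fam}\t{qid}\n")


def read_family_matrix(path, membership_path=None) -> GeneFamilyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    membership: dict[str, list[str]] = {}
    if membership_path is not None:
        mdf = pd.read_csv(membership_path, sep="\t")
        for fam, grp in mdf.groupby("family", sort=False):
            membership[fam] = list(grp["gene"])
    return GeneFamilyMatrix(
        families=list(df.index),
        genomes=list(df.columns),
        counts=df.to_numpy(),
        membership=membership,
    )


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
        path, sep="\t", index_label=""
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(labels=list(df.columns), d=df.to_numpy())


# ---------------------------------------------------------------------------
# configuration and seeding
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg


def derive_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage child seed.

    The child is ``SeedSequence(seed, spawn_key=(crc32(stage),))`` so that
    partial re-runs of a stage reproduce regardless of what ran before.
    """
    return np.random.SeedSequence(seed, spawn_key=(zlib.crc32(stage.encode()),))


def rng_for_stage(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stage))
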