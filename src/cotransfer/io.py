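"""File-level input bundle and provenance-stamped table I/O.

All analysis stages consume a plain-file bundle (the exact dialects the
synthetic-data generator emits): Newick tree, presence/absence TSV, gene
coordinate TSV, genome-length TSV, GO TSV, operon TSV, panel-profile TSV and
an optional truth JSON. Output tables carry a comment header with the
config hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from .phylo import Phylogeny
from .simulate import GroundTruth


def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "family_id"
    if not df.isin([0, 1]).all().all():
        raise ValueError(f"{path}: presence matrix must be 0/1")
    return df.astype(np.int8)


def read_profile_matrix(path) -> pd.DataFrame:
    return read_presence_matrix(path)


def read_genome_lengths(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"genome_id": str})
    return dict(zip(df["genome_id"], df["genome_length"].astype(float)))


def read_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        true_cotransfer_pairs={frozenset(p) for p in data["true_cotransfer_pairs"]},
        true_event_log=[
            (e["branch"], tuple(e["families"]), bool(e["phage"]), float(e["length_bp"]))
            for e in data["true_event_log"]
        ],
        true_cluster_membership=data["true_cluster_membership"],
        true_intra_cluster_distance_samples=data["true_intra_cluster_distance_samples"],
    )


@dataclass
class InputBundle:
    tree: Phylogeny
    presence: pd.DataFrame
    genes: pd.DataFrame
    genome_lengths: dict
    go_map: dict
    operons: dict
    profiles: pd.DataFrame
    truth: GroundTruth | None = None


def load_inputs(indir) -> InputBundle:
    d = Path(indir)
    truth = read_truth(d / "truth.json") if (d / "truth.json").exists() else None
    return InputBundle(
        tree=Phylogeny.read_newick(d / "tree.nwk"),
        presence=read_presence_matrix(d / "presence.tsv"),
        genes=ann.read_gene_table(d / "genes.tsv"),
        genome_lengths=read_genome_lengths(d / "genome_lengths.tsv"),
        go_map=ann.read_go_table(d / "go.tsv"),
        operons=ann.read_operon_table(d / "operons.tsv"),
        profiles=read_profile_matrix(d / "panel_profiles.tsv"),
        truth=truth,
    )


def bundle_from_dataset(ds) -> InputBundle:
    """InputBundle view of an in-memory SimulatedDataset."""
    from .simulate import universe_go

    return InputBundle(
        tree=ds.tree,
        presence=ds.presence,
        genes=ds.genes,
        genome_lengths=ds.genome_lengths,
        go_map=universe_go(ds.universe),
        operons=ds.operons,
        profiles=ds.profiles,
        truth=ds.truth,
    )


# ----------------------------------------------------------------------
def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, cfg_hash: str, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)
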