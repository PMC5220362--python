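"""Genome annotation I/O and phage-association classification.

Gene coordinates are 0-based half-open on a circular chromosome; a feature
wrapping the origin is encoded with ``end > genome_length`` (and
``end - start < genome_length``). Each gene row carries a family id, free
product text and an optional mobile-element flag. Families are classified
into three exclusive phage-association states:

* ``associated`` — any allele has a phage GO term or the keyword (default
  "phage") appears in its product/note text;
* ``not_associated`` — the family has GO terms but no phage evidence;
* ``uncertain`` — no GO terms and no phage evidence.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd

ASSOCIATED = "associated"
NOT_ASSOCIATED = "not_associated"
UNCERTAIN = "uncertain"

GENE_COLUMNS = [
    "family_id",
    "genome_id",
    "start",
    "end",
    "strand",
    "product_text",
    "mobile_element",
]


class AnnotationParseError(ValueError):
    pass


def _validate_genes(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in ("family_id", "genome_id", "start", "end", "strand"):
        if col not in df.columns:
            raise AnnotationParseError(f"{source}: missing column {col!r}")
    if "product_text" not in df.columns:
        df["product_text"] = ""
    if "mobile_element" not in df.columns:
        df["mobile_element"] = 0
    df["product_text"] = df["product_text"].fillna("")
    df["mobile_element"] = df["mobile_element"].fillna(0).astype(int)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise AnnotationParseError(
            f"{source}: end <= start at row {int(bad[0]) + 2}"
            " (wrap-around must be encoded as end > genome_length)"
        )
    dup = df.duplicated(subset=["family_id", "genome_id", "start"])
    if dup.any():
        raise AnnotationParseError(
            f"{source}: duplicate (family, genome, start) at row {int(df.index[dup][0]) + 2}"
        )
    return df[GENE_COLUMNS].reset_index(drop=True)


def read_gene_table(path) -> pd.DataFrame:
    """Read the TSV gene-coordinate dialect (one row per allele)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"family_id": str, "genome_id": str})
    except ValueError as exc:
        raise AnnotationParseError(f"{path}: {exc}") from exc
    return _validate_genes(df, str(path))


def read_gff3(path, genome_id: str | None = None) -> pd.DataFrame:
    """Read gene records from a GFF3 file.

    The family id comes from the ``family`` attribute (falling back to
    ``ID``), the product text from ``product``, the mobile-element flag from
    ``mobile_element``. GFF3 is 1-based inclusive; coordinates are converted
    to the package's 0-based half-open convention.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    def attr(feat, key, default=""):
        vals = feat.attributes.get(key, [])
        return vals[0] if vals else default

    rows = []
    for feat in db.features_of_type("gene"):
        fam = attr(feat, "family", None) or attr(feat, "ID", None)
        if fam is None:
            raise AnnotationParseError(f"{path}: gene without family/ID attribute")
        rows.append(
            {
                "family_id": fam,
                "genome_id": genome_id or feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "product_text": attr(feat, "product"),
                "mobile_element": int(attr(feat, "mobile_element", "0") or 0),
            }
        )
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return _validate_genes(df, str(path))


def write_gff3(genes: pd.DataFrame, genome_lengths: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, L in genome_lengths.items():
            fh.write(f"##sequence-region {gid} 1 {int(L)}\n")
        for _, r in genes.iterrows():
            attrs = (
                f"ID={r.family_id}.{r.genome_id};family={r.family_id};"
                f"product={r.product_text};mobile_element={int(r.mobile_element)}"
            )
            fh.write(
                f"{r.genome_id}\tcotransfer\tgene\t{int(r.start) + 1}\t{int(r.end)}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )


def read_go_table(path) -> dict:
    """GO TSV (family_id, go_term) -> {family_id: set of terms}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"family_id", "go_term"} <= set(df.columns):
        raise AnnotationParseError(f"{path}: need columns family_id, go_term")
    return {fam: set(sub["go_term"]) for fam, sub in df.groupby("family_id")}


def write_go_table(go_map: dict, path) -> None:
    rows = [
        {"family_id": fam, "go_term": term}
        for fam in sorted(go_map)
        for term in sorted(go_map[fam])
    ]
    pd.DataFrame(rows, columns=["family_id", "go_term"]).to_csv(path, sep="\t", index=False)


def read_operon_table(path) -> dict:
    """Operon TSV (genome_id, operon_id, position, family_id) ->
    {genome_id: [ordered [family_id, ...], ...]}. A gene belongs to at most
    one operon per genome."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"position": int})
    need = {"genome_id", "operon_id", "position", "family_id"}
    if not need <= set(df.columns):
        raise AnnotationParseError(f"{path}: need columns {sorted(need)}")
    out: dict = {}
    for gid, sub in df.groupby("genome_id"):
        ops = []
        for _, op in sub.groupby("operon_id"):
            ops.append(list(op.sort_values("position")["family_id"]))
        flat = [f for op in ops for f in op]
        if len(flat) != len(set(flat)):
            raise AnnotationParseError(
                f"{path}: a gene appears in more than one operon of genome {gid}"
            )
        out[gid] = ops
    return out


def write_operon_table(operons: dict, path) -> None:
    rows = []
    for gid in sorted(operons):
        for k, op in enumerate(operons[gid]):
            for pos, fam in enumerate(op):
                rows.append(
                    {"genome_id": gid, "operon_id": f"{gid}_op{k:04d}",
                     "position": pos, "family_id": fam}
                )
    pd.DataFrame(rows, columns=["genome_id", "operon_id", "position", "family_id"]).to_csv(
        path, sep="\t", index=False
    )


def default_phage_go_terms() -> set:
    """Synthetic default list of phage-associated GO terms shipped with the
    package (a stand-in curated for the simulator's vocabulary; real analyses
    should supply their own curated list)."""
    text = resources.files("cotransfer").joinpath("data/phage_go_terms.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")}


def classify_phage(
    genes: pd.DataFrame,
    go_map: dict,
    phage_go_terms: set | None = None,
    keyword: str = "phage",
) -> pd.Series:
    """Three-state phage-association classification per family.

    Family-level status is the OR over alleles: one allele with phage
    evidence makes the whole family ``associated``. Keyword matching is a
    case-insensitive substring test on the product/note text.
    """
    if phage_go_terms is None:
        phage_go_terms = default_phage_go_terms()
    kw = keyword.lower()
    text_hit = (
        genes.assign(hit=genes["product_text"].str.lower().str.contains(kw, regex=False))
        .groupby("family_id")["hit"]
        .any()
    )
    status = {}
    for fam in genes["family_id"].unique():
        terms = go_map.get(fam, set())
        if (terms & phage_go_terms) or bool(text_hit.get(fam, False)):
            status[fam] = ASSOCIATED
        elif terms:
            status[fam] = NOT_ASSOCIATED
        else:
            status[fam] = UNCERTAIN
    return pd.Series(status, name="phage_status")


def write_phage_status(status: pd.Series, path) -> None:
    status.rename_axis("family_id").to_frame().to_csv(path, sep="\t")
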