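"""Candidate-gene extraction and the differential-expression filter.

Gene models intersecting a hotspot's physical interval (any overlap,
1-based inclusive coordinates) are candidate genes; among those, a gene
becomes a stress candidate when, in at least one tissue and one study,
its expression under abiotic stress exceeds the unstressed control by
strictly more than 2 tpm.  Down-regulated genes are never selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hotspots import Hotspot

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "family", "go_terms"]


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features of a GFF3 file as an annotation frame.

    Uses gffutils (in-memory database); keeps ``gene`` features only.
    The description/family is taken from the Name or description
    attribute when present, GO terms from an Ontology_term attribute.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        family = (feat.attributes.get("description") or
                  feat.attributes.get("Name") or [""])[0]
        go = ";".join(feat.attributes.get("Ontology_term", []))
        rows.append((gene_id, feat.seqid, feat.start, feat.end, family, go))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_gff3_genes(ann: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in ann.iterrows():
            attrs = f"ID={r['gene_id']}"
            if r.get("family"):
                attrs += f";description={r['family']}"
            if r.get("go_terms"):
                # GFF3 multi-valued attributes are comma separated
                attrs += ";Ontology_term=" + str(r["go_terms"]).replace(";", ",")
            fh.write(f"{r['chrom']}\tmedscan\tgene\t{int(r['start'])}\t{int(r['end'])}"
                     f"\t.\t+\t.\t{attrs}\n")


def genes_in_hotspot(ann: pd.DataFrame, h: Hotspot,
                     strict_labels: bool = True) -> pd.DataFrame:
    """Gene models whose [start, end] intersects the hotspot bp interval.

    Any overlap counts, boundaries inclusive (a gene starting exactly at
    the interval's right end is included).  The hotspot's chromosome label
    must exist in the annotation unless ``strict_labels`` is off.
    """
    if h.bp_interval is None:
        raise ValueError(f"hotspot {h.name} has no physical interval")
    if strict_labels and h.chromosome not in set(ann["chrom"]) and len(ann):
        raise ValueError(
            f"annotation has no chromosome {h.chromosome!r}; labels present: "
            f"{sorted(set(ann['chrom']))}")
    lo, hi = h.bp_interval
    sub = ann[ann["chrom"] == h.chromosome]
    keep = (sub["start"].to_numpy() <= hi) & (sub["end"].to_numpy() >= lo)
    return sub[keep].reset_index(drop=True)


def annotate_gene_counts(hotspots: Sequence[Hotspot], ann: pd.DataFrame,
                         strict_labels: bool = True) -> list[Hotspot]:
    """Fill ``n_gene_models`` on every hotspot (in place) and return them."""
    for h in hotspots:
        if h.bp_interval is None:
            continue
        h.n_gene_models = len(genes_in_hotspot(ann, h, strict_labels=strict_labels))
    return list(hotspots)


def candidate_gene_table(hotspots: Sequence[Hotspot], ann: pd.DataFrame,
                         strict_labels: bool = True) -> pd.DataFrame:
    """Deduplicated union of gene models over hotspots with a gene->hotspot
    map; genes inside two merged/overlapping hotspots are counted once."""
    frames = []
    for h in hotspots:
        if h.bp_interval is None:
            continue
        sub = genes_in_hotspot(ann, h, strict_labels=strict_labels).copy()
        sub["hotspot"] = h.name
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=list(ANNOTATION_COLUMNS) + ["hotspot"])
    allg = pd.concat(frames, ignore_index=True)
    return allg.drop_duplicates(subset=["gene_id"], keep="first").reset_index(drop=True)


def go_summary(genes: pd.DataFrame) -> pd.DataFrame:
    """Tally of GO terms over a gene set: count and percentage per term,
    with genes lacking any term counted as unclassified."""
    n = len(genes)
    counts: dict[str, int] = {}
    unclassified = 0
    terms_col = genes["go_terms"] if "go_terms" in genes.columns else pd.Series([""] * n)
    for raw in terms_col.fillna(""):
        terms = [t for t in str(raw).split(";") if t]
        if not terms:
            unclassified += 1
            continue
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    rows = [(term, c, 100.0 * c / n if n else 0.0)
            for term, c in sorted(counts.items())]
    rows.append(("unclassified", unclassified,
                 100.0 * unclassified / n if n else 0.0))
    return pd.DataFrame(rows, columns=["term", "n_genes", "pct_genes"])


@dataclass
class CandidateGene:
    gene_id: str
    hotspot: str | None
    tissues: list[str]
    max_delta_tpm: float
    upregulated: bool = True


def deg_filter(genes: pd.DataFrame, expr: pd.DataFrame,
               min_delta_tpm: float = 2.0) -> list[CandidateGene]:
    """Differential-expression candidate filter.

    A gene is selected for a tissue when tpm(stress) - tpm(control)
    strictly exceeds ``min_delta_tpm`` in that tissue in at least one
    study (a delta of exactly the threshold is excluded).  Genes with a
    stress record but no matching control are skipped with a warning.
    Returns CandidateGene records sorted by gene id.
    """
    hotspot_of = {}
    if "hotspot" in genes.columns:
        hotspot_of = dict(zip(genes["gene_id"], genes["hotspot"]))
    wanted = set(genes["gene_id"])
    sub = expr[expr["gene_id"].isin(wanted)]
    wide = sub.pivot_table(index=["gene_id", "tissue", "study"],
                           columns="condition", values="tpm", aggfunc="mean")
    selected: dict[str, CandidateGene] = {}
    skipped: list[str] = []
    for (gene, tissue, _study), row in wide.iterrows():
        stress = row.get("stress", np.nan)
        control = row.get("control", np.nan)
        if np.isnan(control):
            if not np.isnan(stress):
                skipped.append(gene)
            continue
        if np.isnan(stress):
            continue
        delta = stress - control
        if delta > min_delta_tpm:
            cg = selected.setdefault(
                gene, CandidateGene(gene, hotspot_of.get(gene), [], -np.inf))
            if tissue not in cg.tissues:
                cg.tissues.append(tissue)
            cg.max_delta_tpm = max(cg.max_delta_tpm, float(delta))
    if skipped:
        warnings.warn(
            f"genes with stress but no control record skipped: {sorted(set(skipped))}",
            stacklevel=2)
    return [selected[g] for g in sorted(selected)]


def candidates_to_frame(cands: Iterable[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene_id": c.gene_id, "hotspot": c.hotspot,
         "tissues": ";".join(sorted(c.tissues)),
         "max_delta_tpm": c.max_delta_tpm, "upregulated": c.upregulated}
        for c in cands])
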