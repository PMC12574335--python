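"""Candidate-gene windows around QTL and GO term enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def load_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 into a coordinate table.

    Returns a DataFrame with gene_id, chrom, start, end (1-based,
    inclusive), strand and the Name/description attribute when present.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append({
            "gene_id": gene.id,
            "chrom": gene.seqid,
            "start": int(gene.start),
            "end": int(gene.end),
            "strand": gene.strand,
            "label": (gene.attributes.get("Name", [""])[0]
                      or gene.attributes.get("description", [""])[0]),
        })
    return pd.DataFrame(rows,
                        columns=["gene_id", "chrom", "start", "end",
                                 "strand", "label"])


def load_gene2go(path) -> dict:
    """Two-column TSV (gene id, GO term; one pair per line) -> gene -> set."""
    mapping: dict = {}
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["gene_id", "go"])
    for g, t in zip(tab["gene_id"], tab["go"]):
        mapping.setdefault(str(g), set()).add(str(t))
    return mapping


def candidate_genes(qtl_calls, annotation: pd.DataFrame,
                    window_bp: int = 500_000) -> pd.DataFrame:
    """Genes whose bodies intersect +-``window_bp`` around each QTL.

    Intervals are closed on both ends: a gene ending exactly at
    position - window_bp is included.  Returns one row per (QTL, gene).
    """
    ann = annotation.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for q in qtl_calls:
        chrom = getattr(q, "chromosome", None) or q["chromosome"]
        pos = getattr(q, "position_bp", None) or q["position_bp"]
        lo, hi = pos - window_bp, pos + window_bp
        sub = ann[(ann["chrom"].astype(str) == str(chrom))
                  & (ann["end"] >= lo) & (ann["start"] <= hi)]
        for _, g in sub.iterrows():
            rows.append({
                "qtl_chrom": str(chrom), "qtl_pos": int(pos),
                "gene_id": g["gene_id"], "chrom": g["chrom"],
                "start": int(g["start"]), "end": int(g["end"]),
                "strand": g.get("strand", "."),
                "label": g.get("label", ""),
                "distance_bp": int(max(0, max(g["start"] - pos,
                                              pos - g["end"]))),
            })
    return pd.DataFrame(rows, columns=["qtl_chrom", "qtl_pos", "gene_id",
                                       "chrom", "start", "end", "strand",
                                       "label", "distance_bp"])


def go_enrichment(target_flags: dict, gene2go: dict,
                  min_term_size: int = 1) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of GO terms in the target set.

    ``target_flags`` maps every analysed gene to 1 (target) or 0
    (background).  For each term the 2x2 table is
    [[targets with term, targets without], [background with, background
    without]] and the p-value is the 'greater' tail.  Terms are returned
    ranked by ascending p.
    """
    genes = list(target_flags)
    targets = [g for g in genes if target_flags[g]]
    background = [g for g in genes if not target_flags[g]]
    if not targets or not background:
        raise ValueError("need at least one target and one background gene")
    terms = sorted({t for g in genes for t in gene2go.get(g, ())})
    rows = []
    for term in terms:
        a = sum(1 for g in targets if term in gene2go.get(g, ()))
        b = len(targets) - a
        c = sum(1 for g in background if term in gene2go.get(g, ()))
        d = len(background) - c
        if a + c < min_term_size:
            continue
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        rows.append({"go_id": term, "target_with": a, "target_without": b,
                     "background_with": c, "background_without": d,
                     "p": float(p)})
    out = pd.DataFrame(rows, columns=["go_id", "target_with",
                                      "target_without", "background_with",
                                      "background_without", "p"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)
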