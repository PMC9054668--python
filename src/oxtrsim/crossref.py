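"""Differential-expression filtering and ASD gene-category cross-referencing.

Implements Benjamini-Hochberg adjustment, significance/effect-size/direction
filtering of DE tables, and intersection with a category-scored gene list
(categories 1/2/3/other, category 1 = highest confidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("1", "2", "3", "other")
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    pvalue: float | None = None
    padj: float | None = None

    def __post_init__(self):
        if not self.gene_id or not str(self.gene_id).strip():
            raise ValidationError("gene_id must be non-empty")
        for attr in ("pvalue", "padj"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{attr} {v} outside [0, 1]")


@dataclass(frozen=True)
class SfariRecord:
    gene_id: str
    category: str  # "1" | "2" | "3" | "other"
    n_reports: int = 0

    def __post_init__(self):
        if str(self.category) not in CATEGORIES:
            raise ValidationError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.n_reports < 0:
            raise ValidationError("n_reports must be >= 0")


@dataclass
class CrossRefResult:
    n_de: int
    n_asd: int
    category_counts: dict[str, int]
    top: pd.DataFrame  # columns gene_id, category, n_reports, log2fc
    n_duplicates_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "n_de": self.n_de,
            "n_asd": self.n_asd,
            "category_counts": dict(self.category_counts),
            "n_duplicates_dropped": self.n_duplicates_dropped,
            "top": self.top.to_dict(orient="records"),
        }


def normalize_symbol(gene_id: str) -> str:
    return str(gene_id).strip().upper()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj[i] = min over ranks j >= rank(i) of p(j) * n / j, capped at 1,
    returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def filter_degs(
    records: list[DERecord],
    padj_max: float = 0.05,
    abs_lfc_min: float = 1.5,
    direction: str = "both",
) -> list[DERecord]:
    """Keep records with padj < padj_max, |log2fc| >= abs_lfc_min and the
    requested sign; input order is preserved.

    Records lacking padj get it computed from their pvalue via bh_adjust
    (over all such records at once); a record with neither is an error.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    for r in records:
        if r.padj is None and r.pvalue is None:
            raise ValidationError(f"record {r.gene_id!r} lacks both pvalue and padj")

    need = [i for i, r in enumerate(records) if r.padj is None]
    padj = [r.padj for r in records]
    if need:
        adj = bh_adjust([records[i].pvalue for i in need])
        for i, a in zip(need, adj):
            padj[i] = float(a)

    out = []
    for r, a in zip(records, padj):
        if not (a < padj_max):
            continue
        if abs(r.log2fc) < abs_lfc_min:
            continue
        if direction == "up" and r.log2fc <= 0:
            continue
        if direction == "down" and r.log2fc >= 0:
            continue
        out.append(r)
    return out


def _dedup_degs(records: list[DERecord]) -> tuple[dict[str, DERecord], int]:
    """Keep one record per normalized symbol, preferring the smaller padj."""
    best: dict[str, DERecord] = {}
    dropped = 0
    for r in records:
        key = normalize_symbol(r.gene_id)
        if key in best:
            dropped += 1
            cur = best[key]
            a = r.padj if r.padj is not None else (r.pvalue or 1.0)
            b = cur.padj if cur.padj is not None else (cur.pvalue or 1.0)
            if a < b:
                best[key] = r
        else:
            best[key] = r
    return best, dropped


def _dedup_sfari(records: list[SfariRecord]) -> tuple[dict[str, SfariRecord], int]:
    """Keep one record per symbol, preferring the higher-confidence category."""
    best: dict[str, SfariRecord] = {}
    dropped = 0
    for r in records:
        key = normalize_symbol(r.gene_id)
        if key in best:
            dropped += 1
            if _CATEGORY_RANK[str(r.category)] < _CATEGORY_RANK[str(best[key].category)]:
                best[key] = r
        else:
            best[key] = r
    return best, dropped


def crossref_sfari(
    degs: list[DERecord],
    sfari: list[SfariRecord],
    top_n: int = 50,
) -> CrossRefResult:
    """Intersect a (filtered) DE gene set with a category-scored gene list.

    Symbols are matched after upper-casing and whitespace trimming.
    Duplicates within either table are dropped with a logged count (DE:
    smaller padj wins; category list: higher-confidence category wins).
    The top table ranks intersection genes by n_reports descending, ties
    broken by |log2fc| descending then symbol ascending.
    """
    de_map, de_dropped = _dedup_degs(degs)
    sf_map, sf_dropped = _dedup_sfari(sfari)
    n_dropped = de_dropped + sf_dropped
    if n_dropped:
        logger.info("dropped %d duplicate gene rows during cross-reference",
                    n_dropped)

    common = sorted(set(de_map) & set(sf_map))
    counts = {c: 0 for c in CATEGORIES}
    rows = []
    for key in common:
        cat = str(sf_map[key].category)
        counts[cat] += 1
        rows.append({
            "gene_id": key,
            "category": cat,
            "n_reports": int(sf_map[key].n_reports),
            "log2fc": float(de_map[key].log2fc),
        })
    rows.sort(key=lambda r: (-r["n_reports"], -abs(r["log2fc"]), r["gene_id"]))
    top = pd.DataFrame(rows[:top_n],
                       columns=["gene_id", "category", "n_reports", "log2fc"])
    return CrossRefResult(
        n_de=len(de_map),
        n_asd=len(common),
        category_counts=counts,
        top=top,
        n_duplicates_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_de_table(path) -> list[DERecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    if "gene_id" not in df.columns or "log2fc" not in df.columns:
        raise ValidationError("DE table needs columns gene_id and log2fc")

    def opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    return [
        DERecord(
            gene_id=str(row["gene_id"]),
            log2fc=float(row["log2fc"]),
            pvalue=opt(row, "pvalue"),
            padj=opt(row, "padj"),
        )
        for _, row in df.iterrows()
    ]


def read_sfari_table(path) -> list[SfariRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    if "gene_id" not in df.columns or "category" not in df.columns:
        raise ValidationError("gene-category table needs gene_id and category")
    return [
        SfariRecord(
            gene_id=str(row["gene_id"]),
            category=str(row["category"]),
            n_reports=int(row["n_reports"]) if "n_reports" in df.columns else 0,
        )
        for _, row in df.iterrows()
    ]


def write_de_table(path, records: list[DERecord]) -> None:
    pd.DataFrame(
        [{"gene_id": r.gene_id, "log2fc": r.log2fc,
          "pvalue": r.pvalue, "padj": r.padj} for r in records]
    ).to_csv(path, index=False)
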