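"""Calling positively selected genes (PSGs) from per-gene test results.

A gene is a PSG when its unhalved LRT p-value is below the 5% threshold
AND it survives the site-evidence filter: at least one codon site
assigned to class 2a or 2b with posterior probability above 0.5, and —
when more than five such sites exist — a median spacing between
successive sites of at least 10 amino acids.  The spacing rule guards
against clusters of spurious sites at poorly aligned regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BebSite", "GeneTestRecord", "beb_site_filter", "call_psgs", "categorize_psgs"]


@dataclass(frozen=True)
class BebSite:
    """One posterior-flagged site: 1-based amino-acid position, class, posterior."""

    position: int
    site_class: str  # "2a" or "2b"
    posterior: float

    def __post_init__(self):
        if self.site_class not in {"2a", "2b"}:
            raise ValueError("site_class must be '2a' or '2b'")
        if not (0 <= self.posterior <= 1):
            raise ValueError("posterior must lie in [0, 1]")


@dataclass(frozen=True)
class GeneTestRecord:
    """One gene x branch test result row."""

    gene_id: str
    branch: str
    p: float  # unhalved LRT p-value
    beb_sites: tuple[BebSite, ...] = ()
    n_taxa: int | None = None
    alignment_length: int | None = None
    lnL_null: float | None = None
    lnL_alt: float | None = None


@dataclass(frozen=True)
class FilterVerdict:
    retained: bool
    reason: str
    n_sites: int
    median_interval: float | None = None


def beb_site_filter(
    record: GeneTestRecord,
    posterior_threshold: float = 0.5,
    max_unchecked_sites: int = 5,
    min_median_interval: float = 10.0,
) -> FilterVerdict:
    """Site-evidence filter applied to a significant gene.

    Qualifying sites are those in class 2a or 2b with posterior
    strictly above ``posterior_threshold``.  Zero qualifying sites
    rejects the gene.  More than ``max_unchecked_sites`` qualifying
    sites triggers the spacing rule: the median of successive-position
    intervals must be at least ``min_median_interval`` amino acids.
    """
    positions = [s.position for s in record.beb_sites]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError(f"{record.gene_id}: site positions must be strictly increasing")
    qualifying = [
        s.position
        for s in record.beb_sites
        if s.posterior > posterior_threshold
    ]
    n = len(qualifying)
    if n == 0:
        return FilterVerdict(False, "no BEB sites", 0)
    if n <= max_unchecked_sites:
        return FilterVerdict(True, "retained", n)
    intervals = np.diff(qualifying)
    med = float(np.median(intervals))
    if med < min_median_interval:
        return FilterVerdict(False, f"median BEB-site interval {med:g} < {min_median_interval:g}", n, med)
    return FilterVerdict(True, "retained", n, med)


def call_psgs(
    records,
    alpha: float = 0.05,
    posterior_threshold: float = 0.5,
    max_unchecked_sites: int = 5,
    min_median_interval: float = 10.0,
) -> pd.DataFrame:
    """Apply the significance threshold and site filter to a cohort.

    PSG status requires unhalved p strictly below ``alpha`` and a
    retained site-filter verdict.  Returns one row per record with the
    verdict breakdown; per-branch counts are available via
    ``groupby('branch')``.
    """
    rows = []
    for rec in records:
        significant = rec.p < alpha
        if significant:
            verdict = beb_site_filter(
                rec, posterior_threshold, max_unchecked_sites, min_median_interval
            )
            retained, reason = verdict.retained, verdict.reason
            n_sites, med = verdict.n_sites, verdict.median_interval
        else:
            retained, reason = False, "not significant"
            n_sites = sum(1 for s in rec.beb_sites if s.posterior > posterior_threshold)
            med = None
        rows.append(
            {
                "gene_id": rec.gene_id,
                "branch": rec.branch,
                "p": rec.p,
                "significant": significant,
                "n_beb_sites": n_sites,
                "median_interval": med,
                "filter_reason": reason,
                "psg": significant and retained,
            }
        )
    return pd.DataFrame(rows)


def categorize_psgs(psg_table: pd.DataFrame, category_map: dict[str, set[str]]) -> pd.DataFrame:
    """Per-branch x per-category PSG counts (Table-1 style).

    ``category_map`` maps gene id -> set of category names; categories
    may overlap, and a gene in several categories increments each.
    Genes absent from the map contribute to the PSG total only.
    """
    categories = sorted({c for cats in category_map.values() for c in cats})
    rows = []
    for branch, sub in psg_table.groupby("branch", sort=True):
        tested = len(sub)
        psgs = sub[sub["psg"]]
        row = {"branch": branch, "genes_tested": tested, "psgs": len(psgs)}
        for cat in categories:
            row[cat] = int(
                sum(cat in category_map.get(g, set()) for g in psgs["gene_id"])
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["branch", "genes_tested", "psgs", *categories])


def read_category_map(path) -> dict[str, set[str]]:
    """Read a gene -> categories TSV (columns: gene_id, category)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, cat in zip(df["gene_id"], df["category"]):
        out.setdefault(str(gene), set()).add(str(cat))
    return out
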