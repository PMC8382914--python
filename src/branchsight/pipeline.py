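"""Per-gene, per-branch orchestration of the selection scan.

Runs eligibility checks, tree trimming, the branch-site LRT and site
posteriors over a directory of alignments, collecting results and an
exclusion log; downstream, aggregates p-value diagnostics and PSG
summaries.  Per-gene failures are isolated and logged so one bad gene
never aborts a scan; output rows are sorted by gene id so results are
canonical regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import CodonAlignment, read_codon_fasta
from .filters import BebSite, GeneTestRecord, call_psgs, categorize_psgs
from .fit import FitSettings, fit_branch_site
from .posteriors import site_class_posteriors
from .pvalues import mass_at_one, robust_fdr
from .qc import EligibilityRule, check_eligibility, trim_tree
from .trees import ForegroundError, LabeledTree, read_labeled_tree

__all__ = ["AnalysisConfig", "run_branch_scan", "summarize", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

RESULT_COLUMNS = [
    "gene_id",
    "branch",
    "n_taxa",
    "n_codons",
    "lnL_null",
    "lnL_alt",
    "stat",
    "df",
    "p",
    "is_zero",
    "kappa",
    "p0",
    "p1",
    "omega0",
    "omega2",
]


@dataclass(frozen=True)
class BranchDefinition:
    """A named focal branch given by the taxa of its focal clade."""

    name: str
    clade: frozenset[str]
    single_taxon_exempt: bool = False


@dataclass(frozen=True)
class AnalysisConfig:
    """Scan configuration: tree, focal branches, thresholds, optimizer."""

    reference_tree: LabeledTree
    branches: tuple[BranchDefinition, ...]
    alpha: float = 0.05
    truncation_cutoff: float = 0.98
    posterior_threshold: float = 0.5
    max_unchecked_sites: int = 5
    min_median_interval: float = 10.0
    eligibility: EligibilityRule = field(default_factory=EligibilityRule)
    fit_settings: FitSettings = field(default_factory=FitSettings)

    def __post_init__(self):
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise ValueError("branch names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        tree = read_labeled_tree(raw["reference_tree"])
        branches = tuple(
            BranchDefinition(
                name=b["name"],
                clade=frozenset(b["clade"]),
                single_taxon_exempt=bool(b.get("single_taxon_exempt", False)),
            )
            for b in raw["branches"]
        )
        elig = raw.get("eligibility", {})
        fit = raw.get("fit", {})
        exempt = frozenset(
            b.name for b in branches if b.single_taxon_exempt
        )
        return cls(
            reference_tree=tree,
            branches=branches,
            alpha=float(raw.get("alpha", 0.05)),
            truncation_cutoff=float(raw.get("truncation_cutoff", 0.98)),
            posterior_threshold=float(raw.get("posterior_threshold", 0.5)),
            max_unchecked_sites=int(raw.get("max_unchecked_sites", 5)),
            min_median_interval=float(raw.get("min_median_interval", 10.0)),
            eligibility=EligibilityRule(
                min_total_taxa=int(elig.get("min_total_taxa", 10)),
                min_descendants_per_focal_clade=int(
                    elig.get("min_descendants_per_focal_clade", 2)
                ),
                single_taxon_exempt_branches=exempt,
            ),
            fit_settings=FitSettings(
                n_starts=int(fit.get("n_starts", 3)),
                seed=fit.get("seed"),
                branch_mode=fit.get("branch_mode", "joint"),
            ),
        )


@dataclass
class ScanOutput:
    results: pd.DataFrame
    sites: pd.DataFrame  # gene_id, branch, position, site_class, posterior
    exclusions: pd.DataFrame  # gene_id, branch, reason


def run_branch_scan(
    config: AnalysisConfig,
    alignments: dict[str, CodonAlignment],
) -> ScanOutput:
    """Run the branch-site test for every gene x focal branch.

    ``alignments`` maps gene id to codon alignment.  Genes failing
    eligibility for a branch, or whose fit fails, land in the exclusion
    log with a reason; every input gene appears in exactly one of the
    two tables per branch.
    """
    rows, site_rows, excl = [], [], []
    clade_defs = {b.name: set(b.clade) for b in config.branches}
    for gene_id in sorted(alignments):
        aln = alignments[gene_id]
        taxa = set(aln.taxon_ids)
        for branch in config.branches:
            ok, reasons = check_eligibility(
                taxa, {branch.name: clade_defs[branch.name]}, config.eligibility
            )
            if not ok:
                excl.append(
                    {"gene_id": gene_id, "branch": branch.name, "reason": "; ".join(reasons)}
                )
                continue
            try:
                ltree = trim_tree(
                    LabeledTree(
                        tree=config.reference_tree.tree.clone(depth=1),
                        foreground=frozenset(branch.clade),
                    ),
                    taxa,
                )
                fit_null, fit_alt, lrt = fit_branch_site(
                    aln, ltree, config.fit_settings
                )
                post = site_class_posteriors(fit_alt, aln, ltree)
            except (ForegroundError, ValueError) as exc:
                excl.append(
                    {"gene_id": gene_id, "branch": branch.name, "reason": str(exc)}
                )
                continue
            pa = fit_alt.params
            rows.append(
                {
                    "gene_id": gene_id,
                    "branch": branch.name,
                    "n_taxa": aln.n_taxa,
                    "n_codons": aln.n_codons,
                    "lnL_null": lrt.lnL_null,
                    "lnL_alt": lrt.lnL_alt,
                    "stat": lrt.stat,
                    "df": lrt.df,
                    "p": lrt.p,
                    "is_zero": lrt.is_zero,
                    "kappa": pa.kappa,
                    "p0": pa.p0,
                    "p1": pa.p1,
                    "omega0": pa.omega0,
                    "omega2": pa.omega2,
                }
            )
            for _, s in post.iterrows():
                for cls, col in (("2a", "p_class2a"), ("2b", "p_class2b")):
                    if s[col] > config.posterior_threshold:
                        site_rows.append(
                            {
                                "gene_id": gene_id,
                                "branch": branch.name,
                                "position": int(s["position"]),
                                "site_class": cls,
                                "posterior": float(s[col]),
                            }
                        )
    return ScanOutput(
        results=pd.DataFrame(rows, columns=RESULT_COLUMNS),
        sites=pd.DataFrame(
            site_rows, columns=["gene_id", "branch", "position", "site_class", "posterior"]
        ),
        exclusions=pd.DataFrame(excl, columns=["gene_id", "branch", "reason"]),
    )


def records_from_tables(results: pd.DataFrame, sites: pd.DataFrame) -> list[GeneTestRecord]:
    """Join the results and site tables into GeneTestRecord objects."""
    records = []
    grouped = (
        sites.sort_values("position").groupby(["gene_id", "branch"])
        if len(sites)
        else None
    )
    for _, row in results.iterrows():
        key = (row["gene_id"], row["branch"])
        beb = ()
        if grouped is not None and key in grouped.groups:
            sub = grouped.get_group(key)
            merged: dict[int, BebSite] = {}
            for _, s in sub.iterrows():
                pos = int(s["position"])
                cand = BebSite(pos, str(s["site_class"]), float(s["posterior"]))
                if pos not in merged or cand.posterior > merged[pos].posterior:
                    merged[pos] = cand
            beb = tuple(merged[p] for p in sorted(merged))
        records.append(
            GeneTestRecord(
                gene_id=str(row["gene_id"]),
                branch=str(row["branch"]),
                p=float(row["p"]),
                beb_sites=beb,
                n_taxa=int(row["n_taxa"]),
                alignment_length=int(row["n_codons"]),
                lnL_null=float(row["lnL_null"]),
                lnL_alt=float(row["lnL_alt"]),
            )
        )
    return records


def summarize(
    results: pd.DataFrame,
    sites: pd.DataFrame,
    config: AnalysisConfig,
    category_map: dict[str, set[str]] | None = None,
    n_bins: int = 50,
) -> dict:
    """Diagnostics bundle over a scan's results.

    Contains full-range and truncated (p < cutoff) p-value histograms,
    the mass-at-1 proportion, the PSG table before and after the site
    filter, robust-FDR estimates on the pooled sub-cutoff p-values, and
    (when a category map is given) the per-branch category count table.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    p = results["p"].to_numpy()
    edges = np.linspace(0, 1, n_bins + 1)
    hist_full, _ = np.histogram(p, bins=edges)
    trunc = p[p < config.truncation_cutoff]
    hist_trunc, _ = np.histogram(trunc, bins=edges)
    records = records_from_tables(results, sites)
    psg_table = call_psgs(
        records,
        alpha=config.alpha,
        posterior_threshold=config.posterior_threshold,
        max_unchecked_sites=config.max_unchecked_sites,
        min_median_interval=config.min_median_interval,
    )
    rfdr = None
    if (p < config.truncation_cutoff).any():
        rfdr = robust_fdr(p, cutoff=config.truncation_cutoff)
        rfdr = pd.concat(
            [results[["gene_id", "branch"]].reset_index(drop=True), rfdr], axis=1
        )
    out = {
        "n_tests": len(p),
        "mass_at_one": mass_at_one(p),
        "hist_edges": edges,
        "hist_full": hist_full,
        "hist_truncated": hist_trunc,
        "psg_table": psg_table,
        "n_significant": int((psg_table["significant"]).sum()),
        "n_psgs": int(psg_table["psg"].sum()),
        "psgs_per_branch": psg_table.groupby("branch")["psg"].sum().to_dict(),
        "rfdr": rfdr,
    }
    if category_map is not None:
        out["category_counts"] = categorize_psgs(psg_table, category_map)
    return out
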