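import numpy as np
import pandas as pd
import pytest

from branchsight.filters import (
    BebSite,
    GeneTestRecord,
    beb_site_filter,
    call_psgs,
    categorize_psgs,
)


def record(positions, p=0.01, posterior=0.9, gene="g1", branch="A"):
    sites = tuple(BebSite(pos, "2a", posterior) for pos in positions)
    return GeneTestRecord(gene_id=gene, branch=branch, p=p, beb_sites=sites)


def test_no_sites_rejected():
    verdict = beb_site_filter(record([]))
    assert not verdict.retained
    assert "no BEB sites" in verdict.reason


def test_clustered_sites_rejected_by_median_interval():
    """Sites at {3,4,5,6,7,8,150}: seven sites, intervals
    {1,1,1,1,1,142}, median 1 < 10 -> rejected."""
    verdict = beb_site_filter(record([3, 4, 5, 6, 7, 8, 150]))
    assert not verdict.retained
    assert verdict.median_interval == 1.0


def test_spread_sites_retained():
    """Sites at {10,25,40,60,90,130}: six sites, intervals
    {15,15,20,30,40}, median 20 >= 10 -> retained."""
    verdict = beb_site_filter(record([10, 25, 40, 60, 90, 130]))
    assert verdict.retained
    assert verdict.median_interval == 20.0


def test_few_sites_exempt_from_spacing():
    verdict = beb_site_filter(record([5, 6, 7]))  # tightly clustered but only 3
    assert verdict.retained
    assert verdict.median_interval is None


def test_posterior_threshold_strict_and_monotone():
    rec = record([10, 40, 90], posterior=0.5)
    assert not beb_site_filter(rec).retained  # > 0.5 is strict
    rec2 = record([10, 40, 90], posterior=0.51)
    assert beb_site_filter(rec2).retained
    # raising the threshold never grows the retained site count
    high = beb_site_filter(rec2, posterior_threshold=0.6)
    assert high.n_sites <= beb_site_filter(rec2).n_sites


def test_filter_idempotent():
    rec = record([10, 25, 40, 60, 90, 130])
    v1 = beb_site_filter(rec)
    v2 = beb_site_filter(rec)
    assert v1 == v2


def test_nonincreasing_positions_rejected():
    sites = (BebSite(10, "2a", 0.9), BebSite(10, "2b", 0.8))
    rec = GeneTestRecord(gene_id="g", branch="A", p=0.01, beb_sites=sites)
    with pytest.raises(ValueError, match="strictly increasing"):
        beb_site_filter(rec)


def test_psg_threshold_is_strict():
    records = [
        record([10, 40], p=0.049, gene="hit"),
        record([10, 40], p=0.05, gene="boundary"),
        record([10, 40], p=0.2, gene="ns"),
        record([], p=0.01, gene="nosites"),
    ]
    table = call_psgs(records).set_index("gene_id")
    assert bool(table.loc["hit", "psg"])
    assert not table.loc["boundary", "psg"]
    assert not table.loc["ns", "psg"]
    assert not table.loc["nosites", "psg"]
    assert table.loc["ns", "filter_reason"] == "not significant"


def test_cohort_counts_match_hand_tally():
    """100 records with known flags: PSG count equals the tally."""
    rng = np.random.default_rng(7)
    records, expected = [], 0
    for i in range(100):
        p = float(rng.uniform(0, 0.1))
        n_sites = int(rng.integers(0, 4))
        positions = sorted(rng.choice(np.arange(1, 200), size=n_sites, replace=False).tolist())
        records.append(record(positions, p=p, gene=f"g{i}"))
        expected += (p < 0.05) and n_sites > 0
    table = call_psgs(records)
    assert int(table["psg"].sum()) == expected


def test_categorize_counts_overlapping_membership():
    records = [
        record([10, 40], p=0.01, gene="g1", branch="A"),
        record([10, 40], p=0.01, gene="g2", branch="A"),
        record([10, 40], p=0.5, gene="g3", branch="A"),
        record([10, 40], p=0.01, gene="g4", branch="B"),
        record([], p=0.01, gene="g5", branch="B"),
    ]
    table = call_psgs(records)
    cats = {
        "g1": {"lipid", "digestion"},
        "g2": {"lipid"},
        "g4": set(),
        "g3": {"digestion"},
    }
    counts = categorize_psgs(table, cats).set_index("branch")
    assert counts.loc["A", "psgs"] == 2
    assert counts.loc["A", "lipid"] == 2
    assert counts.loc["A", "digestion"] == 1  # g1 counted in both categories
    assert counts.loc["B", "psgs"] == 1
    assert counts.loc["B", "lipid"] == 0
    assert counts.loc["A", "genes_tested"] == 3
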