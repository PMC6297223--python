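"""Shared fixtures: simulated cohorts are expensive, so they are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cnvhic.genome import build_genome_model, make_bins
from cnvhic.matrix import bin_pairs_to_matrix, combine_group, depth_normalize, filter_pairs
from cnvhic.simulate import CohortConfig, capture_config, simulate_cohort


@pytest.fixture(scope="session")
def toy_model():
    """One 50-Mbp chromosome with the default-geometry 3-Mbp deletion."""
    return build_genome_model(
        {"chr22s": 50_000_000}, [("chr22s", 18_500_000, 21_500_000, "H1")]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (5 deletion / 6 control), no allele tags."""
    return simulate_cohort(CohortConfig(seed=11), with_tags=False)


@pytest.fixture(scope="session")
def cohort_matrices(default_cohort):
    """Filtered, binned (500 kbp), depth-scaled matrices plus group means."""
    data = default_cohort
    cfg = data.config
    bins = make_bins(data.genome, cfg.trans_resolution)
    mats, raws = {}, {}
    for sid, _ in data.samples:
        filt, _ = filter_pairs(data.pairs[sid], data.genome,
                               cfg.library_fragment_length, "standard")
        raw = bin_pairs_to_matrix(filt, bins, sid)
        raws[sid] = raw
        mats[sid] = depth_normalize(raw, 1e7)
    del_mean = combine_group([mats[s] for s, g in data.samples if g == "del"])
    ctrl_mean = combine_group([mats[s] for s, g in data.samples if g == "ctrl"])
    return {"bins": bins, "mats": mats, "raws": raws,
            "del_mean": del_mean, "ctrl_mean": ctrl_mean}


@pytest.fixture(scope="session")
def capture_cohort():
    """Deep single-chromosome cohort (1 deletion / 1 control) with tags."""
    return simulate_cohort(capture_config(seed=7), with_tags=True)


@pytest.fixture(scope="session")
def capture_assigned(capture_cohort):
    """Haplotype-assigned, haplotype-filtered pairs for both capture samples."""
    from cnvhic.haplotype import assign_pairs

    data = capture_cohort
    cfg = data.config
    out = {}
    for sid in ("del1", "ctrl1"):
        assigned, report = assign_pairs(data.pairs[sid], data.tags[sid],
                                        data.variants[sid])
        filt, _ = filter_pairs(assigned, data.genome,
                               cfg.library_fragment_length, "haplotype")
        out[sid] = {"assigned": assigned, "filtered": filt, "report": report}
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
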