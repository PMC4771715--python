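import numpy as np
import pytest

from cotarget.pipeline import PipelineConfig, run_pipeline
from cotarget.simulate import PlantedTruth, SimConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default-scale synthetic bundle (seed 1), shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=1)
    paths = generate_bundle(cfg, outdir)
    truth = PlantedTruth.from_json(paths["planted_truth"])
    return cfg, paths, truth


@pytest.fixture(scope="session")
def pipeline_summary(default_bundle, tmp_path_factory):
    """Full pipeline run on the default bundle."""
    _cfg, paths, truth = default_bundle
    outdir = tmp_path_factory.mktemp("pipeline_out")
    pc = PipelineConfig(
        peaks_a=str(paths["peaks_a"]),
        peaks_b=str(paths["peaks_b"]),
        coverage_a=str(paths["coverage_a"]),
        coverage_b=str(paths["coverage_b"]),
        annotation=str(paths["annotation"]),
        expression=str(paths["expression"]),
        design=str(paths["design"]),
        outdir=str(outdir),
    )
    summary = run_pipeline(pc)
    return summary, outdir, truth


def brute_spearman_rho(x, y):
    """Independent rank-correlation oracle: explicit average ranks +
    explicit product-moment formula, no scipy."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def brute_interval_sum(track, chrom, start, end):
    """Per-base loop oracle for coverage sums."""
    return sum(track.value_at(chrom, p) for p in range(start, end))
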