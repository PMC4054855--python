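"""Shared fixtures: small simulated worlds, generated at test time."""

import numpy as np
import pytest

import physmap as pm


@pytest.fixture(scope="session")
def clean_world():
    """Small noise-free arm with assembled contigs (~150 clones, 4x)."""
    cfg = pm.SimulationConfig(
        chromosome_length=5_000, n_clones=150, n_genes=60,
        n_markers={"ISBP": 40, "SSR": 8},
        band_noise=pm.BandNoise(0.0, 0.0, 0.0), seed=11)
    chrom = pm.simulate_chromosome(cfg)
    clones = pm.simulate_bac_library(chrom, cfg)
    fps = pm.simulate_fingerprints(clones, chrom, cfg)
    result = pm.assemble_contigs(fps)
    return {
        "cfg": cfg,
        "chrom": chrom,
        "clones": clones,
        "clone_by_id": {c.id: c for c in clones},
        "fps": fps,
        "fp_by_id": {f.clone_id: f for f in fps},
        "assembly": result,
        "validated": [c for c in result.contigs if c.validated],
    }


@pytest.fixture(scope="session")
def deconv_world():
    """Medium noise-free arm with MTP pools, for deconvolution tests."""
    cfg = pm.SimulationConfig(
        chromosome_length=20_000, n_clones=800, n_genes=150,
        n_markers={"ISBP": 450, "SSR": 50},
        band_noise=pm.BandNoise(0.0, 0.0, 0.0), seed=2)
    chrom = pm.simulate_chromosome(cfg)
    clones = pm.simulate_bac_library(chrom, cfg)
    fps = pm.simulate_fingerprints(clones, chrom, cfg)
    result = pm.assemble_contigs(fps)
    validated = [c for c in result.contigs if c.validated]
    mtp, _ = pm.select_mtp(validated, fps)
    scheme = pm.build_pooling(mtp)
    clone_by_id = {c.id: c for c in clones}
    return {
        "cfg": cfg,
        "chrom": chrom,
        "clones": clones,
        "clone_by_id": clone_by_id,
        "fps": fps,
        "fp_by_id": {f.clone_id: f for f in fps},
        "validated": validated,
        "mtp": mtp,
        "mtp_clones": [clone_by_id[c] for c in mtp],
        "scheme": scheme,
    }


def make_tiling_fingerprints(n_clones, clone_len_kb=120.0, step_kb=45.0,
                             band_per_kb=0.9, seed=0, chrom_extra_kb=50.0):
    """A clean tiling of overlapping clones over synthetic band sites.

    Returns (fingerprints, intervals dict). Band sizes are drawn once per
    site, so overlapping clones share exactly the bands in their
    intersection.
    """
    rng = np.random.default_rng(seed)
    length = step_kb * (n_clones - 1) + clone_len_kb + chrom_extra_kb
    n_sites = rng.poisson(band_per_kb * length)
    pos = np.sort(rng.uniform(0, length, n_sites))
    size = rng.uniform(5_000, 50_000, n_sites)  # mobility units
    fps = []
    intervals = {}
    for i in range(n_clones):
        start = i * step_kb
        end = start + clone_len_kb
        sel = (pos >= start) & (pos < end)
        cid = f"t{i:03d}"
        fps.append(pm.Fingerprint(cid, size[sel]))
        intervals[cid] = (start, end)
    return fps, intervals
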