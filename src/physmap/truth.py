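"""Synthetic ground truth: chromosome arm, BAC library, fingerprints.

Generates a linear chromosome arm carrying restriction-band sites, genes
(with orthologs in three reference grass-like genomes and a
centromere->telomere gradient of non-syntenic genes), markers, terminal
deletion breakpoints and a piecewise recombination profile, plus a redundant
clone library and noisy band fingerprints. Every downstream stage of the
pipeline (assembly, pooling, anchoring, synteny, gene-space statistics) can
be exercised and scored against this truth.

Coordinates are 0-based, half-open, in kb; fractional positions are
kb / arm length. Band identity is size-only: consumers see multisets of
band sizes, never site identities, as with real gels.

All randomness derives from ``config.seed``. Each operation draws from its
own child stream (``default_rng([seed, stream_id])``) so results are
deterministic regardless of the order operations are called in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

# Child-stream identifiers, fixed for reproducibility.
_STREAM_CHROMOSOME = 1
_STREAM_LIBRARY = 2
_STREAM_FINGERPRINTS = 3

#: Mobility units per bp. Capillary fingerprinting sizes fragments to
#: ~0.01 bp, so band sizes are emitted in centi-bp: the 50-500 bp scoring
#: window spans 5,000-50,000 units of the 60,000-unit gel, and a matching
#: tolerance of 12 units means 0.12 bp.
SIZE_SCALE = 100.0

#: Reference genomes genes may have orthologs in.
REFERENCE_GENOMES = ("rice", "brachypodium", "sorghum")

#: Fraction of the arm where the reference synteny switches chromosomes
#: (proximal bins are collinear with one reference chromosome, distal bins
#: with another, as seen in grass comparative maps).
SYNTENY_SWITCH_FRACTION = 0.47

#: Probability that a non-syntenic gene still has a (dispersed) homolog in a
#: given reference genome.
_NONSYNTENIC_HIT_PROB = 0.7

MARKER_CLASSES = ("ISBP", "SSR", "COS", "gene")


@dataclass
class TruthGene:
    id: str
    pos: float  # kb
    syntenic: bool
    #: genome id -> (reference chromosome, reference gene id, index along chr)
    ortholog_refs: dict = field(default_factory=dict)


@dataclass
class TruthMarker:
    id: str
    marker_class: str
    pos: float  # kb
    polymorphic: bool

    def __post_init__(self):
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")


@dataclass
class TruthClone:
    id: str
    start: float  # kb
    end: float  # kb

    @property
    def length(self) -> float:
        return self.end - self.start

    def covers(self, pos_kb: float) -> bool:
        return self.start <= pos_kb < self.end


@dataclass
class TruthChromosome:
    length: float  # kb
    band_pos: np.ndarray  # sorted site positions, kb
    band_size: np.ndarray  # true fragment size per site, bp
    genes: list
    markers: list
    breakpoints: tuple
    recomb_profile: tuple

    def fraction(self, pos_kb: float) -> float:
        return pos_kb / self.length

    def genetic_position(self, pos_kb) -> float:
        return genetic_position(self, pos_kb)


# ---------------------------------------------------------------------------
# chromosome

def _gradient_positions(rng, n, length, gradient):
    """Positions with linearly increasing expected density d0 -> d1.

    Inverse-CDF sampling of the density f(x) proportional to
    d0 + (d1 - d0) x on [0, 1].
    """
    d0, d1 = gradient
    u = rng.random(n)
    if abs(d1 - d0) < 1e-12:
        frac = u
    else:
        a = (d1 - d0) / 2.0
        # solve a x^2 + d0 x - u * (a + d0) = 0 for x in [0, 1]
        c = -u * (a + d0)
        frac = (-d0 + np.sqrt(d0 * d0 - 4 * a * c)) / (2 * a)
    return frac * length


def simulate_chromosome(config: SimulationConfig) -> TruthChromosome:
    """Generate the ground-truth arm: band sites, genes, markers.

    Band sites follow a Poisson process at ``band_density`` per kb with
    fragment sizes uniform in ``band_size_range``. Gene density increases
    linearly centromere -> telomere per ``density_gradient``; with
    probability ``island_clustering`` a gene is instead placed within one
    mean insert of an already-placed gene. The non-syntenic flag is drawn
    with probability interpolated from ``nonsyntenic_gradient`` at the
    gene's fractional position.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_CHROMOSOME])
    length = config.chromosome_length

    # restriction-band sites: Poisson process
    n_sites = rng.poisson(config.band_density * length)
    band_pos = np.sort(rng.uniform(0.0, length, n_sites))
    lo, hi = config.band_size_range
    band_size = rng.uniform(lo, hi, n_sites)

    genes = _simulate_genes(rng, config, length)
    markers = _simulate_markers(rng, config, length)

    return TruthChromosome(
        length=length,
        band_pos=band_pos,
        band_size=band_size,
        genes=genes,
        markers=markers,
        breakpoints=tuple(config.deletion_breakpoints),
        recomb_profile=tuple(config.recomb_profile),
    )


def _simulate_genes(rng, config, length):
    n = config.n_genes
    positions = np.empty(n)
    base = _gradient_positions(rng, n, length, config.density_gradient)
    cluster = rng.random(n) < config.island_clustering
    offsets = rng.uniform(-config.mean_insert, config.mean_insert, n)
    anchor_pick = rng.random(n)
    for i in range(n):
        if i > 0 and cluster[i]:
            anchor = positions[int(anchor_pick[i] * i)]
            positions[i] = np.clip(anchor + offsets[i], 0.0, length)
        else:
            positions[i] = base[i]

    order = np.argsort(positions, kind="stable")
    p0, p1 = config.nonsyntenic_gradient
    genes = []
    # order-preserving reference indices per (genome, reference chromosome)
    counters: dict = {}
    nonsyn_draw = rng.random(n)
    idx_steps = rng.integers(1, 4, size=(n, len(REFERENCE_GENOMES)))
    for rank, j in enumerate(order):
        pos = positions[j]
        frac = pos / length
        nonsyn_p = p0 + (p1 - p0) * frac
        syntenic = nonsyn_draw[j] >= nonsyn_p
        refs = {}
        side = "prox" if frac < SYNTENY_SWITCH_FRACTION else "dist"
        for gi, genome in enumerate(REFERENCE_GENOMES):
            if syntenic:
                chrom = f"{genome}_{side}"
                key = (genome, chrom)
                counters[key] = counters.get(key, 0) + int(idx_steps[rank, gi])
                index = counters[key]
                refs[genome] = (chrom, f"{chrom}_g{index}", index)
            elif rng.random() < _NONSYNTENIC_HIT_PROB:
                chrom = f"{genome}_chr{rng.integers(3, 8)}"
                index = int(rng.integers(0, 5000))
                refs[genome] = (chrom, f"{chrom}_g{index}", index)
        genes.append(
            TruthGene(id=f"g{rank:05d}", pos=float(pos), syntenic=bool(syntenic),
                      ortholog_refs=refs)
        )
    return genes


def _simulate_markers(rng, config, length):
    markers = []
    for cls in sorted(config.n_markers):
        count = config.n_markers[cls]
        pos = np.sort(rng.uniform(0.0, length, count))
        polymorphic = rng.random(count) < config.polymorphic_rate
        for i in range(count):
            markers.append(
                TruthMarker(id=f"{cls.lower()}{i:05d}", marker_class=cls,
                            pos=float(pos[i]), polymorphic=bool(polymorphic[i]))
            )
    return markers


# ---------------------------------------------------------------------------
# BAC library

def simulate_bac_library(chrom: TruthChromosome,
                         config: SimulationConfig) -> list:
    """Random clone library: uniform starts, truncated-normal insert sizes."""
    if config.n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng([config.seed, _STREAM_LIBRARY])
    n = config.n_clones
    inserts = rng.normal(config.mean_insert, config.sd_insert, n)
    # redraw below-minimum inserts rather than clumping them at the floor
    bad = inserts < config.min_insert
    while bad.any():
        inserts[bad] = rng.normal(config.mean_insert, config.sd_insert,
                                  int(bad.sum()))
        bad = inserts < config.min_insert
    inserts = np.minimum(inserts, chrom.length)
    starts = rng.uniform(0.0, chrom.length - inserts)
    width = len(str(n - 1))
    return [
        TruthClone(id=f"c{i:0{width}d}", start=float(starts[i]),
                   end=float(starts[i] + inserts[i]))
        for i in range(n)
    ]


def library_coverage(clones, chrom_length: float) -> float:
    """Total insert length over arm length (e.g. ~15x at full library scale)."""
    return sum(c.length for c in clones) / chrom_length


# ---------------------------------------------------------------------------
# fingerprints

def simulate_fingerprints(clones, chrom: TruthChromosome,
                          config: SimulationConfig) -> list:
    """Noisy band fingerprints: true in-clone bands minus drops, plus
    spurious bands, with Gaussian sizing jitter; sizes clipped to the
    configured scoring window. Band sizes are emitted in mobility units
    (``SIZE_SCALE`` units per bp; jitter SD is in the same units).
    Returns ``assembly.Fingerprint`` objects."""
    from .assembly import Fingerprint

    rng = np.random.default_rng([config.seed, _STREAM_FINGERPRINTS])
    noise = config.band_noise
    lo, hi = (config.band_size_range[0] * SIZE_SCALE,
              config.band_size_range[1] * SIZE_SCALE)
    out = []
    for clone in clones:
        i0, i1 = np.searchsorted(chrom.band_pos, [clone.start, clone.end])
        sizes = chrom.band_size[i0:i1] * SIZE_SCALE
        if noise.drop_rate > 0:
            sizes = sizes[rng.random(sizes.size) >= noise.drop_rate]
        else:
            sizes = sizes.copy()
        if noise.size_jitter_sd > 0 and sizes.size:
            sizes = sizes + rng.normal(0.0, noise.size_jitter_sd, sizes.size)
        if noise.spurious_rate > 0:
            n_spur = rng.poisson(noise.spurious_rate * max(i1 - i0, 1))
            if n_spur:
                sizes = np.concatenate([sizes, rng.uniform(lo, hi, n_spur)])
        sizes = np.clip(sizes, lo, hi)
        out.append(Fingerprint(clone_id=clone.id, bands=np.sort(sizes)))
    return out


# ---------------------------------------------------------------------------
# genetic positions

def genetic_position(chrom: TruthChromosome, pos_kb) -> float:
    """Cumulative genetic position (cM): piecewise-linear integral of the
    recombination profile. ``genetic_position(chrom, 0) == 0``."""
    pos = np.asarray(pos_kb, dtype=float)
    if np.any(pos < 0) or np.any(pos > chrom.length + 1e-9):
        raise ValueError("position outside the chromosome arm")
    frac = pos / chrom.length
    cm = np.zeros_like(frac)
    arm_mb = chrom.length / 1000.0
    for (lo, hi), rate in chrom.recomb_profile:
        overlap = np.clip(frac, lo, hi) - lo
        cm = cm + np.maximum(overlap, 0.0) * arm_mb * rate
    return float(cm) if np.isscalar(pos_kb) else cm


def contigs_from_intervals(clones) -> list:
    """Merge clones into tiling 'contigs' by interval overlap (sweep).

    Returns [(start kb, end kb, member clone ids), ...] for the connected
    components of the truth overlap relation. At sub-tiling coverage this
    yields a realistic contig-size spectrum without fingerprint assembly,
    which is useful for exercising the anchoring stages at full arm scale.
    """
    ordered = sorted(clones, key=lambda c: (c.start, c.id))
    contigs = []
    cur_lo = cur_hi = None
    members: list = []
    for c in ordered:
        if cur_hi is None or c.start < cur_hi:
            cur_lo = c.start if cur_lo is None else cur_lo
            cur_hi = c.end if cur_hi is None else max(cur_hi, c.end)
            members.append(c.id)
        else:
            contigs.append((cur_lo, cur_hi, members))
            cur_lo, cur_hi, members = c.start, c.end, [c.id]
    if members:
        contigs.append((cur_lo, cur_hi, members))
    return contigs


def deletion_line_presence(chrom: TruthChromosome, pos_kb: float) -> list:
    """Presence of a locus across the terminal deletion lines, ordered by
    increasing breakpoint. A line with breakpoint b retains [0, b*length),
    so the locus is present iff pos < b*length."""
    return [pos_kb < b * chrom.length for b in chrom.breakpoints]
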