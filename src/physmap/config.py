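"""Simulation configuration for the synthetic chromosome-arm ground truth.

The defaults describe a wheat-like chromosome arm at full scale: a ~535 Mb
arm carried by a redundant BAC library (inserts ~129 +/- 29 kb), SNaPshot-style
restriction-band fingerprints (~107 scored bands per clone, sizes restricted
to 50-500 bp), eight terminal-deletion breakpoints defining nine deletion
bins, and a three-zone recombination profile (suppressed pericentromeric
recombination, a distal increase to ~1 cM/Mb). Tests and examples pass
scaled-down values; the fields, not the scale, define the model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


#: Terminal-deletion breakpoints (fraction of arm length) defining nine bins.
DEFAULT_BREAKPOINTS = (0.23, 0.32, 0.47, 0.61, 0.69, 0.74, 0.85, 0.89)

#: Piecewise-constant recombination profile: (fraction interval, cM/Mb).
#: ~63% of the arm recombines at 0.05 cM/Mb, the next 21% at 0.20, the
#: distal 16% at 1.0, integrating to ~125 cM on a 535 Mb arm.
DEFAULT_RECOMB_PROFILE = (
    ((0.0, 0.63), 0.05),
    ((0.63, 0.84), 0.20),
    ((0.84, 1.0), 1.0),
)


@dataclass
class BandNoise:
    """Fingerprint noise model.

    drop_rate
        probability that a true band is not scored.
    spurious_rate
        expected spurious bands per true band in the window.
    size_jitter_sd
        SD of the Gaussian sizing error per scored band, in mobility
        units (0.01 bp); 3 units = 0.03 bp, well inside the matching
        tolerance of 12 units.
    """

    drop_rate: float = 0.02
    spurious_rate: float = 0.02
    size_jitter_sd: float = 3.0

    def validate(self) -> None:
        if not (0.0 <= self.drop_rate <= 1.0):
            raise ValueError(f"drop_rate must be in [0,1], got {self.drop_rate}")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        if self.size_jitter_sd < 0:
            raise ValueError("size_jitter_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Ground-truth generator parameters (kb units, fractions of arm length)."""

    chromosome_length: float = 535_000.0  # kb
    centromere_pos: float = 0.0  # kb; the arm is measured away from it
    #: clones yielding usable fingerprints (fingerprinting failures are not
    #: modelled); with 129 kb inserts this is ~15.7x coverage of the arm
    n_clones: int = 65_413
    mean_insert: float = 129.0  # kb
    sd_insert: float = 29.0  # kb
    min_insert: float = 10.0  # kb, truncation floor for insert sizes
    band_density: float = 0.83  # expected bands per kb (~107 per 129 kb clone)
    band_size_range: tuple[float, float] = (50.0, 500.0)  # bp
    band_noise: BandNoise = field(default_factory=BandNoise)
    n_markers: dict[str, int] = field(
        default_factory=lambda: {"ISBP": 475, "SSR": 67, "COS": 3}
    )
    n_genes: int = 1161
    #: probability a new gene is placed within one mean insert of an
    #: already-placed gene (gene-island clustering)
    island_clustering: float = 0.5
    #: linear relative gene density at (centromere, telomere); the observed
    #: bin-level density roughly doubles towards the telomere
    density_gradient: tuple[float, float] = (1.0, 2.0)
    #: proportion of non-syntenic genes at (centromere, telomere)
    nonsyntenic_gradient: tuple[float, float] = (0.45, 0.75)
    #: probability a marker is polymorphic in the mapping population
    polymorphic_rate: float = 0.15
    deletion_breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS
    recomb_profile: tuple = DEFAULT_RECOMB_PROFILE
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.mean_insert <= 0 or self.sd_insert < 0:
            raise ValueError("insert size parameters must be positive")
        lo, hi = self.band_size_range
        if not (50.0 <= lo < hi <= 500.0):
            raise ValueError(
                "band_size_range must lie within [50, 500] bp and be increasing"
            )
        if isinstance(self.band_noise, dict):
            self.band_noise = BandNoise(**self.band_noise)
        self.band_noise.validate()
        bps = tuple(self.deletion_breakpoints)
        if any(not (0.0 < b < 1.0) for b in bps):
            raise ValueError("deletion breakpoints must lie in (0,1)")
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("deletion breakpoints must be strictly increasing")
        self._validate_recomb_profile()
        if not (0.0 <= self.island_clustering <= 1.0):
            raise ValueError("island_clustering must be in [0,1]")
        for p in self.nonsyntenic_gradient:
            if not (0.0 <= p <= 1.0):
                raise ValueError("nonsyntenic_gradient proportions must be in [0,1]")
        if min(self.density_gradient) <= 0:
            raise ValueError("density_gradient values must be positive")

    def _validate_recomb_profile(self) -> None:
        segs = sorted(self.recomb_profile, key=lambda s: s[0][0])
        if not segs:
            raise ValueError("recomb_profile must not be empty")
        pos = 0.0
        for (lo, hi), rate in segs:
            if abs(lo - pos) > 1e-9 or hi <= lo:
                raise ValueError(
                    "recomb_profile intervals must partition [0,1] without gaps"
                )
            if rate < 0:
                raise ValueError("recombination rates must be >= 0")
            pos = hi
        if abs(pos - 1.0) > 1e-9:
            raise ValueError("recomb_profile must end at fraction 1.0")

    # -- (de)serialization ---------------------------------------------------

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        if "band_noise" in d and isinstance(d["band_noise"], dict):
            d["band_noise"] = BandNoise(**d["band_noise"])
        for key in ("band_size_range", "density_gradient", "nonsyntenic_gradient",
                    "deletion_breakpoints"):
            if key in d:
                d[key] = tuple(d[key])
        if "recomb_profile" in d:
            d["recomb_profile"] = tuple(
                (tuple(interval), rate) for interval, rate in d["recomb_profile"]
            )
        return cls(**d)

    def scaled(self, fraction: float) -> "SimulationConfig":
        """A copy with the arm, clone count, marker and gene counts scaled down.

        Per-kb densities, noise, gradients and the recombination profile are
        kept; only extensive quantities shrink.
        """
        if not (0 < fraction <= 1):
            raise ValueError("fraction must be in (0,1]")
        return dataclasses.replace(
            self,
            chromosome_length=self.chromosome_length * fraction,
            n_clones=max(1, int(round(self.n_clones * fraction))),
            n_genes=max(1, int(round(self.n_genes * fraction))),
            n_markers={k: max(1, int(round(v * fraction)))
                       for k, v in self.n_markers.items()},
            band_noise=dataclasses.replace(self.band_noise),
        )
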