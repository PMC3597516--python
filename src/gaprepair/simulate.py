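"""Mechanistic event simulator for gap-repair cohorts.

Generates synthetic recombination events whose heteroduplex geometry
follows the pattern predicted for each repair route, plus overdispersed
per-transformation colony counts, so every downstream stage can be
exercised — and parameter recovery tested — without external data.

Truth labels are generator-side only: DHJ_DISSOLUTION and DOUBLE_SDSA
deliberately produce identical observable patterns (bidirectional
plasmid heteroduplex, clean donor), documenting that the two routes are
not distinguishable from sequence data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

from .efficiency import TransformationRecord
from .hdna import AlleleCalls, AlleleRole
from .substrate import Side, SnpMap

__all__ = [
    "Mechanism",
    "TractLengthModel",
    "SimParams",
    "TransformationSimParams",
    "EventRecord",
    "simulate_event",
    "simulate_cohort",
    "simulate_transformation_counts",
]


class Mechanism(enum.Enum):
    """Generator-side truth label for one simulated event."""

    SDSA = "SDSA"
    DHJ_DISSOLUTION = "DHJ_DISSOLUTION"
    DOUBLE_SDSA = "DOUBLE_SDSA"
    HJ_CLEAVAGE_NCO = "HJ_CLEAVAGE_NCO"
    HJ_CLEAVAGE_CO = "HJ_CLEAVAGE_CO"
    CONVERSION_ONLY = "CONVERSION_ONLY"
    NO_TRANSFER = "NO_TRANSFER"


@dataclass(frozen=True)
class TractLengthModel:
    """Heteroduplex extent in bp beyond a gap edge.

    Default family is geometric (support ``min_bp + 1, min_bp + 2, ...``
    with mean ``mean_bp``): tract lengths decay monotonically, and the
    whole model is configurable so no biological claim is baked in.
    ``min_bp`` exists chiefly for tests that need guaranteed marker
    coverage.
    """

    mean_bp: float = 150.0
    min_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_bp < 0:
            raise ValueError("min_bp must be nonnegative")
        if self.mean_bp <= self.min_bp:
            raise ValueError("mean_bp must exceed min_bp")

    @property
    def _p(self) -> float:
        return 1.0 / (self.mean_bp - self.min_bp)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw tract lengths (bp beyond the gap edge)."""
        return self.min_bp + rng.geometric(self._p, size=size)

    def cdf(self, length_bp: float) -> float:
        """P(tract length <= length_bp)."""
        return float(_st.geom.cdf(np.floor(length_bp) - self.min_bp, self._p))

    def coverage_probability(self, distance_bp: int) -> float:
        """P(tract reaches a marker ``distance_bp`` from the gap edge)."""
        return 1.0 - self.cdf(distance_bp - 1)


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation parameters.

    ``mechanism_weights`` may be keyed by :class:`Mechanism` or by name;
    the pseudo-key ``"HJ_CLEAVAGE"`` is split into the CO and NCO
    cleavage outcomes by ``co_fraction_given_cleavage``.
    ``mmr_repair_prob`` is the per-mismatch probability that a
    heteroduplex site is repaired before replication (to recipient or
    donor base, equiprobably); the default 0 models the
    mismatch-repair-deficient assay background.
    """

    mechanism_weights: Mapping = field(
        default_factory=lambda: {Mechanism.SDSA: 0.89, Mechanism.DHJ_DISSOLUTION: 0.11}
    )
    tract_model: TractLengthModel = field(default_factory=TractLengthModel)
    n_events: int = 100
    co_fraction_given_cleavage: float = 0.5
    mmr_repair_prob: float = 0.0
    seed: int = 0
    strain: str = "WT"

    def resolved_weights(self) -> dict[Mechanism, float]:
        """Normalize keys to :class:`Mechanism` and validate the simplex."""
        out: dict[Mechanism, float] = {m: 0.0 for m in Mechanism}
        for key, w in self.mechanism_weights.items():
            w = float(w)
            if w < 0:
                raise ValueError("mechanism weights must be nonnegative")
            if isinstance(key, Mechanism):
                out[key] += w
            elif key == "HJ_CLEAVAGE":
                out[Mechanism.HJ_CLEAVAGE_CO] += w * self.co_fraction_given_cleavage
                out[Mechanism.HJ_CLEAVAGE_NCO] += w * (1 - self.co_fraction_given_cleavage)
            else:
                out[Mechanism(key)] += w
        total = sum(out.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mechanism weights sum to {total}, expected 1")
        return out


@dataclass(frozen=True)
class TransformationSimParams:
    """Parameters for simulating per-transformation colony counts."""

    n_transformations: int = 12
    true_repair_efficiency: float = 1.0
    leu_mean: float = 200.0
    dispersion: float = 0.1
    mix_id: int = 1
    seed: int = 0
    strain: str = "WT"

    def __post_init__(self) -> None:
        if self.n_transformations < 1:
            raise ValueError("n_transformations must be positive")
        if self.true_repair_efficiency < 0:
            raise ValueError("true_repair_efficiency must be nonnegative")
        if self.leu_mean <= 0:
            raise ValueError("leu_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


@dataclass(frozen=True)
class EventRecord:
    """One simulated transformant.

    ``plasmid_calls``/``chromosome_calls`` are pipe-separated code
    strings (see :mod:`gaprepair.hdna`); they are empty for CO events,
    which are never sequenced in this assay design (the sequencing
    plasmid yields only viable NCOs).
    """

    event_id: str
    strain: str
    truth_mechanism: Mechanism
    stability_call: str  # "CO" or "NCO"
    plasmid_calls: str
    chromosome_calls: str

    def alleles(self, snp_map: SnpMap) -> tuple[AlleleCalls, AlleleCalls]:
        return (
            AlleleCalls.from_string(self.plasmid_calls, AlleleRole.PLASMID, snp_map),
            AlleleCalls.from_string(self.chromosome_calls, AlleleRole.CHROMOSOME, snp_map),
        )


def _covered_mask(side: Side, tract_bp: int, snp_map: SnpMap) -> np.ndarray:
    """Boolean mask over all map SNPs covered by a tract of ``tract_bp``
    extending outward from the gap edge on ``side``."""
    pos = np.asarray(snp_map.snp_positions)
    if side is Side.LEFT:
        dist = snp_map.gap_start - pos
        on_side = pos < snp_map.gap_start
    else:
        dist = pos - snp_map.gap_end
        on_side = pos > snp_map.gap_end
    return on_side & (dist <= tract_bp)


def _apply_mmr(codes: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    if prob <= 0:
        return codes
    h = codes == "H"
    repaired = h & (rng.random(codes.size) < prob)
    to_donor = rng.random(codes.size) < 0.5
    codes = codes.copy()
    codes[repaired & to_donor] = "D"
    codes[repaired & ~to_donor] = "R"
    return codes


def simulate_event(
    mechanism: Mechanism,
    snp_map: SnpMap,
    params: SimParams,
    rng: np.random.Generator,
    event_id: str = "",
) -> EventRecord:
    """Simulate one transformant under a fixed repair route.

    Heteroduplex placement follows the route's predicted topology:
    SDSA marks plasmid SNPs on one uniformly chosen side (the annealing
    side) contiguously outward from the gap over a drawn tract length;
    dissolution and double-SDSA mark both plasmid sides with independent
    lengths; NCO-forming cleavage marks one plasmid side and the
    opposite donor side; conversion-only writes donor-base codes on the
    plasmid; no-transfer leaves everything as recipient base.  A SNP is
    heteroduplex iff the drawn tract interval covers it.
    """
    if not isinstance(mechanism, Mechanism):
        raise ValueError(f"unknown mechanism: {mechanism!r}")
    n = snp_map.n_snps
    plasmid = np.full(n, "R", dtype="<U1")
    chrom = np.full(n, "R", dtype="<U1")
    model = params.tract_model
    stability = "NCO"

    if mechanism is Mechanism.SDSA:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        plasmid[_covered_mask(side, int(model.sample(rng)), snp_map)] = "H"
    elif mechanism in (Mechanism.DHJ_DISSOLUTION, Mechanism.DOUBLE_SDSA):
        for side in (Side.LEFT, Side.RIGHT):
            plasmid[_covered_mask(side, int(model.sample(rng)), snp_map)] = "H"
    elif mechanism is Mechanism.HJ_CLEAVAGE_NCO:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        plasmid[_covered_mask(side, int(model.sample(rng)), snp_map)] = "H"
        chrom[_covered_mask(side.opposite(), int(model.sample(rng)), snp_map)] = "H"
    elif mechanism is Mechanism.HJ_CLEAVAGE_CO:
        stability = "CO"
    elif mechanism is Mechanism.CONVERSION_ONLY:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        plasmid[_covered_mask(side, int(model.sample(rng)), snp_map)] = "D"
    elif mechanism is Mechanism.NO_TRANSFER:
        pass

    if stability == "CO":
        p_str = c_str = ""
    else:
        plasmid = _apply_mmr(plasmid, params.mmr_repair_prob, rng)
        chrom = _apply_mmr(chrom, params.mmr_repair_prob, rng)
        k = snp_map.n_left
        p_str = "".join(plasmid[:k]) + "|" + "".join(plasmid[k:])
        c_str = "".join(chrom[:k]) + "|" + "".join(chrom[k:])

    return EventRecord(
        event_id=event_id,
        strain=params.strain,
        truth_mechanism=mechanism,
        stability_call=stability,
        plasmid_calls=p_str,
        chromosome_calls=c_str,
    )


def simulate_cohort(params: SimParams, snp_map: SnpMap) -> list[EventRecord]:
    """Simulate ``params.n_events`` transformants, mechanisms i.i.d. from
    the resolved weight vector.  Fully reproducible under a fixed seed."""
    weights = params.resolved_weights()
    rng = np.random.default_rng(params.seed)
    mechanisms = list(weights)
    probs = np.array([weights[m] for m in mechanisms])
    draws = rng.choice(len(mechanisms), size=params.n_events, p=probs)
    width = max(4, len(str(params.n_events)))
    return [
        simulate_event(
            mechanisms[d], snp_map, params, rng, event_id=f"E{i + 1:0{width}d}"
        )
        for i, d in enumerate(draws)
    ]


def simulate_transformation_counts(
    params: TransformationSimParams, rng: np.random.Generator | None = None
) -> list[TransformationRecord]:
    """Simulate per-transformation His+ and Leu+ colony counts.

    Each transformation shares a gamma-distributed culture factor
    (mean 1, variance ``dispersion``) multiplying both selection counts,
    giving negative-binomial-like overdispersion; His+ counts are
    Poisson with mean ``true_repair_efficiency x leu_mean x factor``.
    Leu+ draws of zero are rejected (the record invariant requires a
    positive denominator).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    records = []
    for _ in range(params.n_transformations):
        if params.dispersion > 0:
            g = rng.gamma(1.0 / params.dispersion, params.dispersion)
        else:
            g = 1.0
        leu = int(rng.poisson(params.leu_mean * g))
        while leu == 0:
            leu = int(rng.poisson(params.leu_mean * g))
        his = int(rng.poisson(params.true_repair_efficiency * params.leu_mean * g))
        records.append(
            TransformationRecord(
                strain=params.strain, mix_id=params.mix_id, his_count=his, leu_count=leu
            )
        )
    return records
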