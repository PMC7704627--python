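"""Synthetic promoter studies with planted motif instances and ground truth.

The generator emulates the statistical structure of a two-group
comparative promoter study: ``n_active`` + ``n_inactive`` species
(default 14 + 14), one upstream window per species (default 1000 bp)
drawn i.i.d. from a background composition, and, per matrix, motif
instances sampled from the matrix frequencies and planted with
group-specific probabilities at offsets drawn from a truncated discrete
Gaussian (so positional concentration, e.g. around -175, can be
emulated).  Plants overwrite the background in place — promoter length
and offset arithmetic are preserved — and never overlap each other;
chance background hits remain possible by design, as in real promoters.

Every planted instance is recorded in a truth table together with its
Match-style scores against its own matrix, so downstream recall can
distinguish plants that score above a profile's cut-offs from
sub-threshold ones.  All randomness flows from a single seed; outputs
are byte-stable per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ACTIVE,
    BASES,
    INACTIVE,
    FrequencyMatrix,
    PromoterSequence,
    SpeciesMeta,
    StudyError,
    revcomp,
)
from .scan import core_similarity, matrix_similarity

_RETRY_CAP = 1000


@dataclass(frozen=True)
class PlantSpec:
    """Planting parameters for one matrix.

    ``plant_prob_active``/``plant_prob_inactive`` are per-species
    probabilities of receiving an instance (per attempt, with
    ``max_plants_per_promoter`` attempts); offsets are drawn from a
    Gaussian with ``position_mean``/``position_sd`` in upstream-offset
    units, rounded and truncated to offsets where the window fits, or
    uniformly over all valid offsets when ``uniform_positions`` is set.
    """

    matrix_id: str
    plant_prob_active: float
    plant_prob_inactive: float
    position_mean: float = -175.0
    position_sd: float = 15.0
    max_plants_per_promoter: int = 1
    uniform_positions: bool = False

    def __post_init__(self):
        for name in ("plant_prob_active", "plant_prob_inactive"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise StudyError(f"{name} must be in [0, 1], got {p}")
        if self.max_plants_per_promoter < 0:
            raise StudyError("max_plants_per_promoter must be >= 0")

    def prob_for(self, state: str) -> float:
        return self.plant_prob_active if state == ACTIVE else self.plant_prob_inactive


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped generator configuration (defaults: 14/14 x 1000 bp)."""

    n_active: int = 14
    n_inactive: int = 14
    promoter_length: int = 1000
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plants: tuple[PlantSpec, ...] = ()
    seed: int = 0
    active_prefix: str = "act"
    inactive_prefix: str = "inact"
    group_label_active: str = ""
    group_label_inactive: str = ""

    def __post_init__(self):
        if self.n_active < 0 or self.n_inactive < 0:
            raise StudyError("group sizes must be non-negative")
        if not 1 <= self.promoter_length <= 1000:
            raise StudyError("promoter_length must be in 1..1000")
        bg = np.asarray(self.background_freqs, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise StudyError("background_freqs must be 4 probabilities summing to 1")


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted instance.

    ``instance`` is the sampled motif-sense string; on the minus strand
    its reverse complement occupies the forward window at ``offset``.
    ``mss``/``css`` are the instance's Match-style scores against its own
    matrix, so sub-threshold plants can be identified for any cut-off.
    """

    species_id: str
    matrix_id: str
    offset: int
    strand: str
    instance: str
    mss: float
    css: float


@dataclass
class SyntheticStudy:
    promoters: list[PromoterSequence]
    meta: list[SpeciesMeta]
    truth: list[PlantRecord]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def sample_motif_instance(matrix: FrequencyMatrix, rng: np.random.Generator) -> str:
    """Draw one instance, base i ~ f(i, .)."""
    f = matrix.frequencies
    u = rng.random(len(matrix))
    picks = (f.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    return "".join(BASES[i] for i in picks)


def _draw_offset(spec: PlantSpec, lo: int, hi: int, occupied: list[tuple[int, int]],
                 length: int, rng: np.random.Generator) -> int | None:
    """One offset in [lo, hi] whose window avoids occupied intervals."""
    for _ in range(_RETRY_CAP):
        if spec.uniform_positions:
            v = int(rng.integers(lo, hi + 1))
        else:
            v = int(round(rng.normal(spec.position_mean, spec.position_sd)))
            if not lo <= v <= hi:
                continue
        if all(v + length <= s or v >= e for s, e in occupied):
            return v
    return None


def generate_study(config: SyntheticConfig,
                   matrices: list[FrequencyMatrix]) -> SyntheticStudy:
    """Generate promoters, metadata and plant truth for one study.

    Species are processed in a fixed order (actives then inactives) and
    plant specs in configuration order, so output is byte-stable per
    seed.  An impossible placement after the retry cap raises an error
    naming the species and matrix.
    """
    by_id = {m.matrix_id: m for m in matrices}
    for spec in config.plants:
        if spec.matrix_id not in by_id:
            raise StudyError(f"plant spec references unknown matrix {spec.matrix_id!r}")
        if len(by_id[spec.matrix_id]) > config.promoter_length:
            raise StudyError(
                f"matrix {spec.matrix_id!r} is longer than the promoter")
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background_freqs, dtype=float)
    width = max(2, len(str(max(config.n_active, config.n_inactive))))
    roster = (
        [(f"{config.active_prefix}{i + 1:0{width}d}", ACTIVE,
          config.group_label_active) for i in range(config.n_active)]
        + [(f"{config.inactive_prefix}{i + 1:0{width}d}", INACTIVE,
            config.group_label_inactive) for i in range(config.n_inactive)]
    )
    promoters: list[PromoterSequence] = []
    meta: list[SpeciesMeta] = []
    truth: list[PlantRecord] = []
    L_prom = config.promoter_length
    for sid, state, group in roster:
        codes = rng.choice(4, size=L_prom, p=bg)
        occupied: list[tuple[int, int]] = []
        for spec in config.plants:
            matrix = by_id[spec.matrix_id]
            L_m = len(matrix)
            lo, hi = -L_prom, -L_m
            p = spec.prob_for(state)
            for _ in range(spec.max_plants_per_promoter):
                if rng.random() >= p:
                    continue
                instance = sample_motif_instance(matrix, rng)
                v = _draw_offset(spec, lo, hi, occupied, L_m, rng)
                if v is None:
                    raise StudyError(
                        f"could not place an instance of {spec.matrix_id!r} in "
                        f"{sid!r} after {_RETRY_CAP} attempts")
                strand = "+" if rng.random() < 0.5 else "-"
                placed = instance if strand == "+" else revcomp(instance)
                start = v + L_prom
                codes[start:start + L_m] = [BASES.index(b) for b in placed]
                occupied.append((v, v + L_m))
                truth.append(PlantRecord(
                    species_id=sid, matrix_id=spec.matrix_id, offset=v,
                    strand=strand, instance=instance,
                    mss=matrix_similarity(matrix, instance),
                    css=core_similarity(matrix, instance),
                ))
        bases = "".join(BASES[c] for c in codes)
        promoters.append(PromoterSequence(species_id=sid, bases=bases,
                                          origin_note="synthetic"))
        meta.append(SpeciesMeta(species_id=sid, telomerase_state=state,
                                group_label=group))
    return SyntheticStudy(promoters=promoters, meta=meta, truth=truth,
                          config=config)


def merge_studies(studies: list[SyntheticStudy]) -> SyntheticStudy:
    """Concatenate disjoint sub-studies (species ids must not collide)."""
    seen: set[str] = set()
    for s in studies:
        ids = {m.species_id for m in s.meta}
        if ids & seen:
            raise StudyError(f"species id collision: {sorted(ids & seen)}")
        seen |= ids
    return SyntheticStudy(
        promoters=[p for s in studies for p in s.promoters],
        meta=[m for s in studies for m in s.meta],
        truth=[t for s in studies for t in s.truth],
        config=studies[0].config if studies else None,
    )


def truth_frame(study: SyntheticStudy) -> pd.DataFrame:
    return pd.DataFrame(
        [{"species_id": t.species_id, "matrix_id": t.matrix_id,
          "offset": t.offset, "strand": t.strand, "instance": t.instance,
          "mss": t.mss, "css": t.css} for t in study.truth],
        columns=["species_id", "matrix_id", "offset", "strand", "instance",
                 "mss", "css"],
    )


def write_truth(study: SyntheticStudy) -> str:
    return truth_frame(study).to_csv(sep="\t", index=False, float_format="%.12g")


def subthreshold_truth(study: SyntheticStudy, mss_cutoff: float,
                       core_cutoff: float = 0.0) -> list[PlantRecord]:
    """Plants whose own-matrix scores fall below the given cut-offs."""
    return [t for t in study.truth
            if t.mss < mss_cutoff or t.css < core_cutoff]


# ---------------------------------------------------------------------------
# Example matrices (synthetic constructions, not database matrices)

_SOFT = {  # low-information flank columns, counts out of 20
    "a": [8, 4, 4, 4], "c": [4, 8, 4, 4], "g": [4, 4, 8, 4], "t": [4, 4, 4, 8],
}
_DET = {  # deterministic columns
    "A": [20, 0, 0, 0], "C": [0, 20, 0, 0], "G": [0, 0, 20, 0], "T": [0, 0, 0, 20],
}


def _matrix_from_pattern(mid: str, name: str, pattern: str) -> FrequencyMatrix:
    """Uppercase letters are deterministic positions, lowercase soft."""
    rows = [_DET[ch] if ch.isupper() else _SOFT[ch] for ch in pattern]
    return FrequencyMatrix(matrix_id=mid, factor_name=name,
                           counts=np.array(rows, dtype=float))


def example_matrices() -> list[FrequencyMatrix]:
    """Four synthetic motif matrices shaped like well-known TF families.

    These are constructed for simulation and testing only — the patterns
    are invented around published consensus flavours (ETS GGAA core,
    E-box CAGGTG, GATA WGATAR) and are *not* derived from TRANSFAC,
    JASPAR or any other database.  Each matrix has 8 deterministic
    positions (including the whole 5-position core), so sampled
    instances always match them and chance background matches on a 1 kb
    window are rare (~4^-8 per window), plus 4 soft flanking positions
    that give sampled instances realistic score variation.  The 8-mers
    were chosen pairwise distinct (in both orientations) so planted
    instances of one matrix are not hit by another.
    """
    return [
        _matrix_from_pattern("GABPA_SYN", "GABPA-like ETS (synthetic)",
                             "acCCGGAAGTtg"),
        _matrix_from_pattern("ELK1_SYN", "ELK1-like ETS (synthetic)",
                             "gaCCGGAAACca"),
        _matrix_from_pattern("E47_SYN", "E47-like E-box (synthetic)",
                             "ctGCAGGTGTac"),
        _matrix_from_pattern("GATA3_SYN", "GATA3-like (synthetic)",
                             "ttAGATAAGAgc"),
    ]


def five_group_study(seed: int,
                     matrices: list[FrequencyMatrix] | None = None
                     ) -> SyntheticStudy:
    """A 28-species study with five site/state patterns (14 active, 14 inactive).

    Emulates the qualitative group structure a comparative promoter study
    can resolve: five sub-groups, each defined by which motifs its
    promoters carry —

    ===== ========= ======================================
    group state     planted motifs
    ===== ========= ======================================
    I     inactive  E47-like (far upstream, ~ -800)
    II    inactive  E47-like + GATA3-like
    III   inactive  ELK1-like + GATA3-like
    IV    active    GATA3-like
    V     active    GABPA-like (near -175) + ELK1-like
    ===== ========= ======================================

    The GABPA-like motif is concentrated around offset -175 in active
    promoters only; GATA3-like and ELK1-like sites are spread uniformly.
    Group labels are carried in the metadata.
    """
    matrices = matrices if matrices is not None else example_matrices()

    def plant(mid, **kw):
        return PlantSpec(matrix_id=mid, plant_prob_active=1.0,
                         plant_prob_inactive=1.0, **kw)

    e47 = dict(position_mean=-800.0, position_sd=60.0)
    spread = dict(uniform_positions=True)
    gabpa = dict(position_mean=-175.0, position_sd=15.0)
    groups = [
        ("I", INACTIVE, 5, [plant("E47_SYN", **e47)]),
        ("II", INACTIVE, 5, [plant("E47_SYN", **e47), plant("GATA3_SYN", **spread)]),
        ("III", INACTIVE, 4, [plant("ELK1_SYN", **spread), plant("GATA3_SYN", **spread)]),
        ("IV", ACTIVE, 7, [plant("GATA3_SYN", **spread)]),
        ("V", ACTIVE, 7, [plant("GABPA_SYN", **gabpa), plant("ELK1_SYN", **spread)]),
    ]
    child_seeds = np.random.SeedSequence(seed).generate_state(len(groups)) % (2**31)
    studies = []
    for (label, state, n, plants), child in zip(groups, child_seeds):
        cfg = SyntheticConfig(
            n_active=n if state == ACTIVE else 0,
            n_inactive=0 if state == ACTIVE else n,
            plants=tuple(plants), seed=int(child),
            active_prefix=f"g{label}_", inactive_prefix=f"g{label}_",
            group_label_active=label, group_label_inactive=label)
        studies.append(generate_study(cfg, matrices))
    return merge_studies(studies)


def null_config(seed: int, plant_prob: float = 0.5,
                matrix_id: str = "GABPA_SYN", **overrides) -> SyntheticConfig:
    """A no-group-difference study: equal plant probability in both groups."""
    spec = PlantSpec(matrix_id=matrix_id, plant_prob_active=plant_prob,
                     plant_prob_inactive=plant_prob)
    cfg = SyntheticConfig(plants=(spec,), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def effect_config(seed: int, plant_prob_active: float = 0.9,
                  plant_prob_inactive: float = 0.1,
                  matrix_id: str = "GABPA_SYN", **overrides) -> SyntheticConfig:
    """A group-difference study: the matrix favours active promoters."""
    spec = PlantSpec(matrix_id=matrix_id, plant_prob_active=plant_prob_active,
                     plant_prob_inactive=plant_prob_inactive)
    cfg = SyntheticConfig(plants=(spec,), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
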