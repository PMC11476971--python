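"""Synthetic serum-lipidomics cohorts with the study's replicate structure.

The generator emulates a case/control serum lipidomics design: SCH
(schizophrenia) and C (control) individuals of both genders, each injected
in triplicate, measured in a few acquisition batches.  Intensities are
log-normal with two variance components (a per-individual biological
deviation and a smaller per-injection technical deviation), an additive
disease shift on the log10 scale for a subset of features (most of them
decreased in SCH), and a gender shift that — mirroring the cohort this
emulates — is present only within the control class.  Sporadic
missing values and gross outlier injections complete the picture.

All effects are additive on the log10 scale:

    log10 X_ijr = mu_f + disease_f * [class=SCH] + gender_f * [gender=F]
                  + batch_b + u_if + e_ijr

with u ~ N(0, sigma_ind^2) per individual x feature and
e ~ N(0, sigma_rep^2) per injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureTable

# descriptor ranges spanned by the annotated lipids (m/z in Th, rt in min)
MZ_RANGE = (227.0, 1321.0)
RT_RANGE = (0.4, 11.7)

#: stratified corruption pattern of the study-design scenario:
#: the 14 removed chromatograms split as 9 C-M, 1 SCH-M, 4 SCH-F
STUDY_OUTLIER_STRATA = {("C", "M"): 9, ("SCH", "M"): 1, ("C", "F"): 0, ("SCH", "F"): 4}


@dataclass
class CohortConfig:
    """Study-design knobs for :func:`generate_cohort`.

    Defaults describe the emulated cohort: 30 SCH + 31 C individuals
    (15/15 and 16/15 by gender), triplicate injections, 192 features,
    4 batches.  ``disease_effect`` / ``gender_effect`` may be a
    per-feature array of signed log10 shifts or ``None`` to draw the
    default sparse pattern (``n_disease_features`` affected features of
    size ``disease_effect_size``, 70 % decreased in SCH / 30 % increased;
    ``n_gender_features`` of size ``gender_effect_size``).
    """

    n_sch_m: int = 15
    n_sch_f: int = 15
    n_c_m: int = 16
    n_c_f: int = 15
    n_replicates: int = 3
    n_features: int = 192
    n_batches: int = 4
    mu_log: float | np.ndarray | None = None      # baseline log10 location per feature
    sigma_log: float | np.ndarray = 0.15          # individual-level log10 scale
    sigma_rep: float = 0.05                       # injection-level log10 scale
    batch_sd: float = 0.02                        # batch shifts stay negligible
    disease_effect: np.ndarray | None = None
    gender_effect: np.ndarray | None = None
    n_disease_features: int = 40
    disease_effect_size: float = 0.3
    decreased_fraction: float = 0.7
    n_gender_features: int = 30
    gender_effect_size: float = 0.4
    gender_effect_in_controls_only: bool = True
    missing_rate: float = 0.0
    n_outliers: int = 0
    outlier_magnitude: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sch_m", "n_sch_f", "n_c_m", "n_c_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_replicates", "n_features", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0 <= self.missing_rate < 0.5):
            raise ValueError(f"missing_rate must lie in [0, 0.5), got {self.missing_rate}")
        if np.any(np.asarray(self.sigma_log) <= 0):
            raise ValueError("sigma_log must be > 0")
        if self.sigma_rep <= 0:
            raise ValueError(f"sigma_rep must be > 0, got {self.sigma_rep}")
        if self.n_outliers < 0:
            raise ValueError(f"n_outliers must be >= 0, got {self.n_outliers}")

    @property
    def n_individuals(self) -> int:
        return self.n_sch_m + self.n_sch_f + self.n_c_m + self.n_c_f

    @property
    def n_samples(self) -> int:
        return self.n_individuals * self.n_replicates


def _effect_vector(rng, p, n_affected, size, neg_fraction):
    """Sparse signed per-feature shift: `n_affected` features, mixed signs."""
    effect = np.zeros(p)
    n_affected = min(n_affected, p)
    idx = rng.choice(p, size=n_affected, replace=False)
    n_neg = int(round(neg_fraction * n_affected))
    signs = np.r_[-np.ones(n_neg), np.ones(n_affected - n_neg)]
    effect[idx] = signs * size
    return effect


def generate_cohort(config: CohortConfig) -> FeatureTable:
    """Draw one synthetic cohort; bit-identical for a fixed config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_features

    mu = config.mu_log
    if mu is None:
        mu = rng.uniform(4.0, 6.5, size=p)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (p,)).copy()
    sigma_ind = np.broadcast_to(np.asarray(config.sigma_log, dtype=float), (p,)).copy()

    disease = config.disease_effect
    if disease is None:
        disease = _effect_vector(
            rng, p, config.n_disease_features, config.disease_effect_size,
            config.decreased_fraction,
        )
    disease = np.broadcast_to(np.asarray(disease, dtype=float), (p,)).copy()
    gender_eff = config.gender_effect
    if gender_eff is None:
        gender_eff = _effect_vector(rng, p, config.n_gender_features,
                                    config.gender_effect_size, 0.5)
    gender_eff = np.broadcast_to(np.asarray(gender_eff, dtype=float), (p,)).copy()

    # individuals, in a fixed roster order
    roster = (
        [("SCH", "M")] * config.n_sch_m + [("SCH", "F")] * config.n_sch_f
        + [("C", "M")] * config.n_c_m + [("C", "F")] * config.n_c_f
    )
    records = []
    feature_ids = [f"F{j + 1:03d}" for j in range(p)]
    log_rows = []
    batch_shift = rng.normal(0.0, config.batch_sd, size=(config.n_batches, p))
    counters = {}
    sample_pos = 0
    for cls, gender in roster:
        counters[(cls, gender)] = counters.get((cls, gender), 0) + 1
        ind_id = f"{cls}-{gender}{counters[(cls, gender)]:02d}"
        u = rng.normal(0.0, 1.0, size=p) * sigma_ind
        base = mu + u
        if cls == "SCH":
            base = base + disease
        if gender == "F" and (cls == "C" or not config.gender_effect_in_controls_only):
            base = base + gender_eff
        for r in range(1, config.n_replicates + 1):
            batch = sample_pos % config.n_batches + 1
            e = rng.normal(0.0, config.sigma_rep, size=p)
            log_rows.append(base + batch_shift[batch - 1] + e)
            records.append(
                dict(sample_id=f"{ind_id}_r{r}", individual_id=ind_id,
                     replicate_index=r, class_label=cls, gender=gender, batch=batch)
            )
            sample_pos += 1

    log_matrix = np.asarray(log_rows)
    intensities = np.power(10.0, log_matrix)

    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    samples = pd.DataFrame(records).set_index("sample_id")
    features = pd.DataFrame(
        {
            "mz": rng.uniform(*MZ_RANGE, size=p),
            "rt": rng.uniform(*RT_RANGE, size=p),
            "ion_mode": rng.choice(["positive", "negative"], size=p),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = FeatureTable(
        pd.DataFrame(intensities, index=samples.index, columns=feature_ids),
        samples,
        features,
    )
    if config.n_outliers:
        table, _ = inject_outliers(
            table, config.n_outliers, config.outlier_magnitude,
            seed=int(rng.integers(2**31 - 1)),
        )
    return table


def inject_outliers(
    table: FeatureTable,
    n_outliers: int,
    magnitude: float = 2.0,
    seed: int = 0,
    stratum_counts: dict | None = None,
) -> tuple[FeatureTable, list[str]]:
    """Corrupt ``n_outliers`` samples by a gross log10 shift.

    Each corrupted sample has a random half of its features multiplied by
    ``10**magnitude`` (sign drawn per sample), which puts it far from the
    bulk in the orthogonal-distance sense while keeping intensities
    positive.  ``stratum_counts`` maps (class_label, gender) to how many
    samples to corrupt in that stratum (e.g. :data:`STUDY_OUTLIER_STRATA`);
    its values must sum to ``n_outliers``.
    """
    if n_outliers > table.n_samples:
        raise ValueError(
            f"n_outliers ({n_outliers}) exceeds sample count ({table.n_samples})"
        )
    if n_outliers == 0:
        return table.copy(), []
    rng = np.random.default_rng(seed)
    meta = table.samples
    if stratum_counts is not None:
        if sum(stratum_counts.values()) != n_outliers:
            raise ValueError("stratum_counts must sum to n_outliers")
        chosen = []
        for (cls, gender), count in stratum_counts.items():
            pool = meta.index[(meta.class_label == cls) & (meta.gender == gender)]
            if count > len(pool):
                raise ValueError(f"stratum {(cls, gender)} has only {len(pool)} samples")
            chosen.extend(rng.choice(pool, size=count, replace=False))
    else:
        chosen = list(rng.choice(meta.index, size=n_outliers, replace=False))

    out = table.copy()
    p = out.n_features
    factor = 10.0 ** magnitude
    for sid in chosen:
        cols = rng.choice(p, size=p // 2, replace=False)
        sign = rng.choice([-1.0, 1.0])
        out.intensities.iloc[out.intensities.index.get_loc(sid), cols] *= factor ** sign
    return out, [str(s) for s in chosen]


def study_design_config(seed: int = 0, **overrides) -> CohortConfig:
    """The emulated study design: 61 individuals in triplicate, 192 features."""
    defaults = dict(seed=seed, missing_rate=0.02)
    defaults.update(overrides)
    return CohortConfig(**defaults)
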