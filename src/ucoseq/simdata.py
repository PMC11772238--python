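"""Synthetic umbilical-cord-occlusion experiments with known ground truth.

The generator emulates the study design end to end: ten fetal sheep
profiled from whole blood at five timepoints (-1 h baseline, then 6 h,
24 h, 72 h and 7 d = 168 h after occlusion), two treatment arms whose
infusions only distinguish the animals after the 24-h sample, two
QC-dropped samples (one at 72 h, one at 7 d, from distinct vehicle
animals), and a mild/severe injury split across animals.

Counts are negative-binomial mixtures over cell types: each sample has a
latent blood-composition vector on the simplex (symmetric Dirichlet
baseline, concentration 5), each cell type has a mean-expression profile
in which its marker genes are specifically elevated, and the per-gene
mixture mean is scaled to the sample's library size.  Three kinds of
signal can be planted on top, each recorded in a :class:`GroundTruth`
ledger: smooth polynomial-in-time trend effects, injury-class-dependent
effects at a designated timepoint, and post-occlusion logit shifts of
selected cell-type fractions.  Setting every effect to zero yields a pure
null dataset, which downstream calibration tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ucoseq import neuroscore
from ucoseq.core_io import CountMatrix, MarkerTable, SampleTable


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults reproduce the study design."""

    n_animals: int = 10
    timepoints_h: tuple[float, ...] = (-1.0, 6.0, 24.0, 72.0, 168.0)
    n_genes: int = 5000
    n_cell_types: int = 22
    markers_per_type: int = 25
    n_trend_genes: int = 60
    n_injury_genes: int = 10
    trend_effect: float = 2.0     # log2-fold amplitude of the time profile
    injury_effect: float = 1.0    # log2-fold severe-vs-mild shift
    fraction_shift: float = 1.0   # logit shift of affected fractions post-occlusion
    n_shifted_types: int = 3
    treatment_effect: float = 0.0  # log2-fold, active arm post-occlusion (off by default)
    n_treatment_genes: int = 0
    nb_dispersion: float = 0.1    # var = mu + dispersion * mu^2
    libsize_range: tuple[int, int] = (500_000, 1_500_000)
    dropout_samples: tuple[tuple[str, float], ...] | None = None  # None -> default rule
    treatment_fraction: float = 0.5
    mild_fraction: float = 0.4
    dirichlet_concentration: float = 5.0
    marker_specificity: float = 8.0  # fold elevation of a marker in its own type
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints_h)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigError("timepoints_h must be strictly increasing")
        self.timepoints_h = tps
        for name in ("n_animals", "n_genes", "n_cell_types", "markers_per_type"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_trend_genes", "n_injury_genes", "n_treatment_genes",
                     "n_shifted_types"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_shifted_types > self.n_cell_types:
            raise ConfigError("n_shifted_types exceeds n_cell_types")
        for name in ("treatment_fraction", "mild_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigError("libsize_range must be positive and ordered")
        n_special = (self.n_cell_types * self.markers_per_type
                     + self.n_trend_genes + self.n_injury_genes + self.n_treatment_genes)
        if n_special > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_special} marker/planted genes"
            )

    @property
    def n_markers(self) -> int:
        return self.n_cell_types * self.markers_per_type


@dataclass
class GroundTruth:
    """Ledger of everything planted, for recovery tests."""

    trend_genes: pd.DataFrame       # gene_id, direction_6h (up|down), shape
    injury_genes: pd.DataFrame      # gene_id, timepoint_h, sign
    shifted_cell_types: pd.DataFrame  # cell_type, sign
    true_fractions: pd.DataFrame    # sample x cell type, rows on the simplex
    injury_class: pd.Series         # animal_id -> mild|severe
    treatment_genes: pd.DataFrame | None = None


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    samples: SampleTable
    markers: MarkerTable
    truth: GroundTruth
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int, seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def _animal_ids(config: SimulationConfig) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(config.n_animals)]


def _sample_id(animal: str, tp: float) -> str:
    label = "pre" if tp < 0 else (f"{tp:g}h" if tp < 48 else f"{tp / 24:g}d")
    return f"{animal}_{label}"


def assign_design(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Animal-level design: treatment arm and injury class.

    Counts in each arm/class follow the configured fractions exactly
    (rounded), with the assignment shuffled by the seed.
    """
    rng = _rng(config, 11, seed)
    animals = _animal_ids(config)
    n_active = int(round(config.treatment_fraction * config.n_animals))
    n_mild = int(round(config.mild_fraction * config.n_animals))
    arm = np.array(["active"] * n_active + ["vehicle"] * (config.n_animals - n_active))
    cls = np.array(["mild"] * n_mild + ["severe"] * (config.n_animals - n_mild))
    rng.shuffle(arm)
    rng.shuffle(cls)
    return pd.DataFrame({"animal_id": animals, "treatment": arm, "injury_class": cls})


def build_sample_table(config: SimulationConfig, seed: int | None = None) -> SampleTable:
    """Full sample grid minus the QC dropouts."""
    design = assign_design(config, seed)
    rows = []
    for _, a in design.iterrows():
        for tp in config.timepoints_h:
            rows.append(
                {
                    "sample_id": _sample_id(a["animal_id"], tp),
                    "animal_id": a["animal_id"],
                    "timepoint_h": tp,
                    "treatment": a["treatment"],
                    "phase": "pre" if tp < 0 else "post",
                    "injury_class": a["injury_class"],
                }
            )
    df = pd.DataFrame(rows)
    for animal, tp in _dropouts(config, design):
        mask = (df["animal_id"] == animal) & (df["timepoint_h"] == tp)
        if not mask.any():
            raise ConfigError(f"dropout ({animal}, {tp}) not in the sample grid")
        df = df.loc[~mask]
    return SampleTable(df.reset_index(drop=True))


def _dropouts(config: SimulationConfig, design: pd.DataFrame) -> list[tuple[str, float]]:
    if config.dropout_samples is not None:
        return [(a, float(t)) for a, t in config.dropout_samples]
    # default: one 72-h and one 7-d sample from two distinct vehicle animals,
    # so the vehicle-only trend subset loses both (38 = 40 - 2)
    tps = config.timepoints_h
    late = [t for t in tps if t >= 72] or list(tps[-2:])
    vehicle = design.loc[design["treatment"] == "vehicle", "animal_id"].tolist()
    if len(vehicle) < 2:
        vehicle = design["animal_id"].tolist()
    return [(vehicle[0], float(late[0])), (vehicle[1], float(late[-1]))]


# ---------------------------------------------------------------------------
# fractions


def simulate_fractions(
    config: SimulationConfig,
    seed: int | None = None,
    samples: SampleTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample cell-type fractions plus the shifted-type ledger.

    Baseline fractions are symmetric-Dirichlet draws; in post-occlusion
    samples the shifted cell types get ``fraction_shift`` added to their
    component on the logit scale before renormalization, alternating the
    shift's sign across the affected types.
    """
    if samples is None:
        samples = build_sample_table(config, seed)
    rng = _rng(config, 23, seed)
    cell_types = [f"CT{k + 1:02d}" for k in range(config.n_cell_types)]
    alpha = np.full(config.n_cell_types, config.dirichlet_concentration)
    frac = rng.dirichlet(alpha, size=len(samples.data))
    shifted = cell_types[: config.n_shifted_types]
    signs = [1 if i % 2 == 0 else -1 for i in range(len(shifted))]
    post = (samples.data["phase"] == "post").to_numpy()
    if config.fraction_shift != 0 and shifted:
        logit = np.log(frac) - np.log1p(-frac)
        for (ct, sign) in zip(shifted, signs):
            k = cell_types.index(ct)
            logit[post, k] += sign * config.fraction_shift
        shifted_vals = 1.0 / (1.0 + np.exp(-logit[np.ix_(post, [cell_types.index(c) for c in shifted])]))
        frac[np.ix_(post, [cell_types.index(c) for c in shifted])] = shifted_vals
        frac[post] /= frac[post].sum(axis=1, keepdims=True)
    frame = pd.DataFrame(frac, index=samples.data["sample_id"].tolist(), columns=cell_types)
    ledger = pd.DataFrame({"cell_type": shifted, "sign": signs})
    return frame, ledger


# ---------------------------------------------------------------------------
# signature


def simulate_signature(
    config: SimulationConfig, seed: int | None = None
) -> tuple[MarkerTable, pd.DataFrame]:
    """Marker table plus cell-type x gene mean-expression profiles.

    Non-marker genes share one mean across all cell types (so their
    mixture expression is composition-independent — the null backbone);
    each marker gene's mean is elevated ``marker_specificity``-fold in its
    own type only.
    """
    rng = _rng(config, 37, seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    cell_types = [f"CT{k + 1:02d}" for k in range(config.n_cell_types)]
    perm = rng.permutation(config.n_genes)
    marker_idx = perm[: config.n_markers]
    # baseline per-gene mean expression, lognormal over ~3 decades
    base = rng.lognormal(mean=2.0, sigma=1.2, size=config.n_genes)
    profile = np.tile(base, (config.n_cell_types, 1))
    marker_rows = []
    for k, ct in enumerate(cell_types):
        for j in range(config.markers_per_type):
            g = marker_idx[k * config.markers_per_type + j]
            profile[k, g] = base[g] * config.marker_specificity
            marker_rows.append({"marker_gene_id": gene_ids[g], "cell_type": ct,
                                "ortholog_id": pd.NA})
    markers = MarkerTable(pd.DataFrame(marker_rows))
    prof = pd.DataFrame(profile, index=cell_types, columns=gene_ids)
    return markers, prof


# ---------------------------------------------------------------------------
# planted effects


_TREND_SHAPES = ("linear", "peak")


def _trend_profile(shape: str, timepoints: np.ndarray) -> np.ndarray:
    """Polynomial-in-time profile over the timepoints, zero at baseline.

    Shapes are degree <= 2 polynomials of centred/scaled hours — a
    monotone drift ("linear") and a transient excursion vanishing at both
    ends of the window ("peak").  The amplitude is normalized so the
    root-mean-square of the profile over the post-occlusion timepoints is
    one: the planted ``trend_effect`` is then the typical post-occlusion
    log2 shift rather than the (larger) endpoint excursion.
    """
    z = (timepoints - timepoints.mean()) / timepoints.std()
    if shape == "linear":
        f = z
    elif shape == "peak":  # concave parabola, zero at both ends of the window
        f = (z - z.min()) * (z.max() - z)
    else:
        raise ValueError(f"unknown trend shape {shape!r}")
    f = f - f[0]  # anchor at the pre-occlusion baseline
    rms_post = np.sqrt(np.mean(f[1:] ** 2))
    return f / rms_post


def _plant_assignments(config: SimulationConfig, seed: int | None):
    """Disjoint marker / trend / injury / treatment gene index sets."""
    rng = _rng(config, 37, seed)  # same stream as the signature: same permutation
    perm = rng.permutation(config.n_genes)
    i = config.n_markers
    trend = perm[i: i + config.n_trend_genes]
    i += config.n_trend_genes
    injury = perm[i: i + config.n_injury_genes]
    i += config.n_injury_genes
    treat = perm[i: i + config.n_treatment_genes]
    return trend, injury, treat


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Draw the count matrix; returns (counts, samples, ground truth).

    Per sample the relative expression vector is the fraction-weighted
    mixture of cell-type profiles, multiplied by the planted log2 effects,
    renormalized to sum to one and scaled to the sample's library size;
    counts are gamma-Poisson with var = mu + dispersion * mu^2.
    """
    samples = build_sample_table(config, seed)
    frac, shift_ledger = simulate_fractions(config, seed, samples=samples)
    markers, profile = simulate_signature(config, seed)
    rng = _rng(config, 53, seed)

    gene_ids = list(profile.columns)
    tps = np.asarray(config.timepoints_h)
    trend_idx, injury_idx, treat_idx = _plant_assignments(config, seed)

    # trend-gene ledger: shape, sign, direction at 6 h (vs baseline)
    trend_rows = []
    tp6 = tps[1] if len(tps) > 1 else tps[-1]
    shapes = {}
    for g in trend_idx:
        shape = _TREND_SHAPES[rng.integers(len(_TREND_SHAPES))]
        sign = 1 if rng.random() < 0.5 else -1
        prof_t = _trend_profile(shape, tps)
        d6 = sign * (prof_t[list(tps).index(tp6)] - prof_t[0])
        shapes[g] = (shape, sign, prof_t)
        trend_rows.append({"gene_id": gene_ids[g], "shape": shape, "sign": sign,
                           "direction_6h": "up" if d6 > 0 else "down"})
    injury_rows = []
    inj_tps = [t for t in tps if t <= tps[min(1, len(tps) - 1)]]  # baseline and first post point
    for i, g in enumerate(injury_idx):
        tp = inj_tps[i % len(inj_tps)]
        sign = 1 if rng.random() < 0.5 else -1
        injury_rows.append({"gene_id": gene_ids[g], "timepoint_h": tp, "sign": sign})
    treat_rows = [{"gene_id": gene_ids[g], "sign": 1} for g in treat_idx]

    sdf = samples.data
    libsizes = rng.integers(config.libsize_range[0], config.libsize_range[1] + 1,
                            size=len(sdf))
    # mixture of profiles: (samples x types) @ (types x genes)
    mix = frac.loc[sdf["sample_id"]].to_numpy() @ profile.to_numpy()
    log2fx = np.zeros_like(mix)
    tp_of = sdf["timepoint_h"].to_numpy()
    severe = (sdf["injury_class"] == "severe").to_numpy()
    active_post = ((sdf["treatment"] == "active") & (sdf["phase"] == "post")).to_numpy()
    tp_pos = {t: k for k, t in enumerate(tps)}
    for g, (shape, sign, prof_t) in shapes.items():
        log2fx[:, g] += config.trend_effect * sign * prof_t[[tp_pos[t] for t in tp_of]]
    for row in injury_rows:
        g = gene_ids.index(row["gene_id"])
        at_tp = tp_of == row["timepoint_h"]
        log2fx[at_tp & severe, g] += config.injury_effect * row["sign"]
    for row in treat_rows:
        g = gene_ids.index(row["gene_id"])
        log2fx[active_post, g] += config.treatment_effect
    rel = mix * 2.0 ** log2fx
    row_sums = rel.sum(axis=1)
    if (row_sums <= 0).any():
        raise RuntimeError("a sample has zero expected expression for all genes")
    mu = rel / row_sums[:, None] * libsizes[:, None]  # samples x genes

    if config.nb_dispersion > 0:
        shape_param = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape_param, mu / shape_param)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(counts.T, gene_ids, sdf["sample_id"].tolist())
    truth = GroundTruth(
        trend_genes=pd.DataFrame(trend_rows, columns=["gene_id", "shape", "sign", "direction_6h"]),
        injury_genes=pd.DataFrame(injury_rows, columns=["gene_id", "timepoint_h", "sign"]),
        shifted_cell_types=shift_ledger,
        true_fractions=frac,
        injury_class=sdf.drop_duplicates("animal_id").set_index("animal_id")["injury_class"],
        treatment_genes=pd.DataFrame(treat_rows, columns=["gene_id", "sign"]) if treat_rows else None,
    )
    return cm, samples, truth


def simulate_experiment(config: SimulationConfig, seed: int | None = None) -> SimulatedExperiment:
    counts, samples, truth = simulate_counts(config, seed)
    markers, _ = simulate_signature(config, seed)
    return SimulatedExperiment(counts, samples, markers, truth, config)


# ---------------------------------------------------------------------------
# scorecards


def simulate_scorecards(
    config: SimulationConfig,
    seed: int | None = None,
    injury_class: pd.Series | None = None,
) -> list[neuroscore.Scorecard]:
    """Scorecards whose totals land on the correct side of the mild/severe cut.

    Mild animals draw a target total in [2, 9.5], severe in [10.5, 26];
    random cells are then filled with legal component values until the
    running total hits the target exactly (all legal values are multiples
    of 0.5, so any half-point target is reachable).
    """
    if injury_class is None:
        injury_class = assign_design(config, seed).set_index("animal_id")["injury_class"]
    rng = _rng(config, 71, seed)
    cards = []
    cells = [
        (r, s, c)
        for r in neuroscore.REGIONS
        for s in neuroscore.SECTIONS
        for c in neuroscore.COMPONENTS
    ]
    for animal, cls in injury_class.items():
        if cls == "mild":
            target = rng.integers(4, 20) * 0.5          # 2.0 .. 9.5
        else:
            target = rng.integers(21, 53) * 0.5         # 10.5 .. 26.0
        card = neuroscore.Scorecard(animal_id=str(animal))
        order = rng.permutation(len(cells))
        remaining = target
        for idx in order:
            if remaining <= 0:
                break
            r, s, c = cells[idx]
            legal = [v for v in neuroscore.LEGAL_SCORES[c] if 0 < v <= remaining]
            if not legal:
                continue
            v = float(legal[rng.integers(len(legal))])
            card.set(r, s, c, v)
            remaining -= v
        if remaining > 0:  # pad with remaining half points (capacity is ample)
            for idx in order:
                r, s, c = cells[idx]
                if (r, s, c) in card.entries:
                    continue
                v = min(remaining, max(neuroscore.LEGAL_SCORES[c]))
                if v in neuroscore.LEGAL_SCORES[c]:
                    card.set(r, s, c, float(v))
                    remaining -= v
                if remaining <= 0:
                    break
        cards.append(neuroscore.validate(card))
    return cards


# ---------------------------------------------------------------------------
# ortholog map


def simulate_ortholog_map(
    marker_table: MarkerTable, loss_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Cross-species ortholog map with independent marker attrition.

    Each marker is retained with probability ``1 - loss_rate`` and renamed
    to a deterministic target identifier; lost markers are absent from the
    returned map.
    """
    if not 0 <= loss_rate < 1:
        raise ValueError("loss_rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    keep = rng.random(len(marker_table)) >= loss_rate
    df = marker_table.data.loc[keep, ["marker_gene_id"]].copy()
    df["ortholog_id"] = "OAR_" + df["marker_gene_id"]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ground-truth ledger I/O


def write_truth(truth: GroundTruth, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    truth.trend_genes.to_csv(d / "truth_trend_genes.tsv", sep="\t", index=False)
    truth.injury_genes.to_csv(d / "truth_injury_genes.tsv", sep="\t", index=False)
    truth.shifted_cell_types.to_csv(d / "truth_shifted_types.tsv", sep="\t", index=False)
    truth.true_fractions.to_csv(d / "truth_fractions.tsv", sep="\t",
                                index_label="sample_id")
    truth.injury_class.to_frame("injury_class").to_csv(
        d / "truth_injury_class.tsv", sep="\t", index_label="animal_id"
    )
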