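"""Synthetic longitudinal ordinal symptom cohorts with known ground truth.

Generates STAR*D-like data: ~8 groups of depressed subjects observed at
weeks {0, 4, 6, 9, 12}, each visit yielding 16 QIDS-style items (0-3) that
consolidate into 9 ordinal symptom domains, plus a baseline quality-of-life
("context") questionnaire.  The data-generating model is a Gaussian copula:
each visit draws a latent multivariate normal whose correlation structure is
a known Gaussian graphical model (so true partial correlations and true
global strength are available exactly), shifted by a severity mean, and cut
at fixed thresholds into the 0-3 ordinal scale.

Design features emulated from the study population:

- group-varying baseline severity and baseline network strength (the
  inverse strength-vs-change "plasticity" gradient is built in);
- a latent severity trajectory per group peaking at week 9, so the intended
  maximum clinical change lands near each group's change-magnitude bin
  center, with change-phase visits drawn from a *stronger* network;
- a per-subject trait (a latent offset shared across domains and visits)
  giving scores their within-subject stability while leaving every visit's
  cross-sectional correlation matrix — hence the estimated network — intact;
- a baseline context class that moderates the week-12 outcome.

All randomness flows from one master seed via spawned substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .network import NetworkError
from .scoring import DEFAULT_ITEM_MAP, ItemMap

__all__ = [
    "TrueNetworkSpec",
    "GroupConfig",
    "CohortConfig",
    "SyntheticCohort",
    "make_true_network",
    "sample_ordinal_visit",
    "generate_cohort",
    "default_config",
    "null_config",
]

WEEKS = (0, 4, 6, 9, 12)
PHASE_OF_WEEK = {0: "baseline", 4: "baseline", 6: "change", 9: "postchange", 12: "postchange"}


@dataclass(frozen=True)
class TrueNetworkSpec:
    """Ground-truth GGM: a random sparse partial-correlation pattern rescaled
    to an exact target global strength."""

    target_strength: float
    p: int = 9
    density: float = 0.25
    weight_range: tuple[float, float] = (0.5, 1.0)
    positive_edge_prob: float = 0.8
    seed: int = 0


def make_true_network(spec: TrueNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Construct a partial-correlation matrix W with sum of absolute edge
    weights exactly ``target_strength`` and its implied correlation matrix.

    Edges are drawn at the given density with magnitudes in ``weight_range``
    (relative — they are rescaled to hit the target strength) and mostly
    positive signs, as is typical of symptom networks.  The precision matrix
    is I - W; patterns whose precision is not positive definite are redrawn.
    The partial correlations of the returned correlation matrix equal W
    exactly (up to numerical inversion error).
    """
    p = spec.p
    n_pairs = p * (p - 1) // 2
    if spec.density == 0 or spec.target_strength == 0:
        return np.zeros((p, p)), np.eye(p)
    m = max(1, int(round(spec.density * n_pairs)))
    if spec.target_strength > m * 1.0:
        raise NetworkError(
            f"target strength {spec.target_strength} infeasible: at most "
            f"{m} edges of |w| <= 1 (bound {m * 1.0})"
        )
    rng = np.random.default_rng(spec.seed)
    iu = np.triu_indices(p, 1)
    for _ in range(200):
        pick = rng.choice(n_pairs, size=m, replace=False)
        mags = rng.uniform(*spec.weight_range, size=m)
        signs = np.where(rng.random(m) < spec.positive_edge_prob, 1.0, -1.0)
        w = mags * signs
        w *= spec.target_strength / np.abs(w).sum()
        if np.abs(w).max() >= 0.97:
            continue
        W = np.zeros((p, p))
        W[iu[0][pick], iu[1][pick]] = w
        W = W + W.T
        A = np.eye(p) - W  # precision with unit diagonal
        if np.linalg.eigvalsh(A).min() <= 1e-3:
            continue
        cov = np.linalg.inv(A)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        return W, (corr + corr.T) / 2
    raise NetworkError(
        f"could not realize a positive-definite network at strength "
        f"{spec.target_strength}, density {spec.density}; lower the strength "
        f"or raise the density"
    )


def sample_ordinal_visit(
    n: int,
    covariance: np.ndarray,
    thresholds: np.ndarray,
    mean_shift,
    seed=0,
) -> np.ndarray:
    """Draw an n x p ordinal (0-3) matrix from a thresholded latent normal.

    ``thresholds`` is a length-3 strictly increasing cutpoint vector (shared
    by all items) or a p x 3 per-item matrix; ``mean_shift`` is a scalar,
    length-p vector or n x p matrix of latent means.  ``seed`` may be an int
    or a ``numpy`` Generator.
    """
    cov = np.asarray(covariance, dtype=float)
    p = cov.shape[0]
    t = np.atleast_2d(np.asarray(thresholds, dtype=float))
    if t.shape[0] == 1:
        t = np.repeat(t, p, axis=0)
    if t.shape != (p, 3) or not (np.diff(t, axis=1) > 0).all():
        raise ValueError("thresholds must be 3 strictly increasing cutpoints per item")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise NetworkError(f"covariance is not positive definite: {e}") from e
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = rng.standard_normal((n, p)) @ L.T + np.asarray(mean_shift, dtype=float)
    out = (latent[:, :, None] > t[None, :, :]).sum(axis=2)
    return out.astype(int)


@dataclass
class GroupConfig:
    """One change-magnitude group of the synthetic cohort."""

    label: str
    n: int
    target_delta: float  # intended group mean maximum change (bin center)
    baseline_total: float  # intended group mean baseline QIDS total
    strength_baseline: float
    strength_change: float
    strength_postchange: float
    density: float = 0.25
    subject_delta_sd: float = 1.0


@dataclass
class CohortConfig:
    """Full parameterization of the generator (the study conditions)."""

    groups: list[GroupConfig]
    thresholds: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    p_good_context: float = 0.5
    context_coef: float = 1.15  # week-12 improvement multiplier, good context
    week_fracs: dict = field(
        default_factory=lambda: {4: 0.45, 6: 0.7, 9: 1.0, 12: 0.8}
    )
    trait_var_cap: float = 0.45  # per-subject trait variance upper bound
    p_female: float = 0.62  # female fraction, similar in every group
    qlesq_mean: float = 45.0
    qlesq_sd: float = 9.0
    seed: int = 42

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["groups"] = [GroupConfig(**g) for g in raw["groups"]]
        raw["week_fracs"] = {int(k): float(v) for k, v in raw["week_fracs"].items()}
        if isinstance(raw.get("thresholds"), list):
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)


def default_config(n_per_group: int = 350, seed: int = 42) -> CohortConfig:
    """The default study conditions: eight groups whose true baseline
    strengths decrease 2.4 -> 1.0 while their intended change magnitudes
    increase 0.5 -> 20 (the built-in plasticity gradient); change-phase
    strengths rise above baseline in proportion to the change magnitude."""
    targets = (0.5, 2.5, 4.5, 6.5, 8.5, 10.5, 12.5, 19.0)
    base_s = np.linspace(2.4, 1.0, 8)
    labels = ("[0-1]", "[2-3]", "[4-5]", "[6-7]", "[8-9]", "[10-11]", "[12-13]", "[16-24]")
    # the top group covers a 9-unit change range, the others 2 units each
    sds = (1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 2.8)
    groups = []
    for k, (tgt, bs, lab, sd) in enumerate(zip(targets, base_s, labels, sds)):
        rise = 0.2 + 1.2 * tgt / 20.0
        groups.append(
            GroupConfig(
                label=lab,
                n=n_per_group,
                target_delta=tgt,
                baseline_total=12.0 + 0.6 * tgt,
                strength_baseline=float(bs),
                strength_change=float(bs + rise),
                strength_postchange=float(bs + rise),
                subject_delta_sd=sd,
            )
        )
    return CohortConfig(groups=groups, seed=seed)


def null_config(n_per_group: int = 350, seed: int = 42) -> CohortConfig:
    """All generator effects switched off: equal strengths everywhere, flat
    trajectories, no context moderation."""
    groups = [
        GroupConfig(
            label=f"null{k}",
            n=n_per_group,
            target_delta=0.0,
            baseline_total=13.0,
            strength_baseline=1.7,
            strength_change=1.7,
            strength_postchange=1.7,
        )
        for k in range(8)
    ]
    return CohortConfig(groups=groups, context_coef=1.0, seed=seed)


@dataclass
class SyntheticCohort:
    """Generated long-format records plus the ground-truth sidecar."""

    records: pd.DataFrame
    ground_truth: dict
    true_networks: dict  # (group label, phase) -> partial-correlation matrix

    def write(self, csv_path, json_path=None) -> None:
        self.records.to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def _domain_mean_grid(thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # expected ordinal score as a function of latent mean, for inversion
    ms = np.linspace(-6.0, 6.0, 4001)
    e = norm.cdf(ms[:, None] - np.asarray(thresholds)[None, :]).sum(axis=1)
    return ms, e


def _qids_items_from_domains(
    dom: np.ndarray, item_map: ItemMap, rng: np.random.Generator
) -> np.ndarray:
    """Emit 16-item responses whose max-consolidation reproduces ``dom``:
    the first item of each domain carries the score, the rest draw <= it."""
    n = dom.shape[0]
    items = np.zeros((n, 16), dtype=int)
    for j, idxs in enumerate(item_map.domains.values()):
        items[:, idxs[0] - 1] = dom[:, j]
        for extra in idxs[1:]:
            items[:, extra - 1] = rng.integers(0, dom[:, j] + 1)
    return items


def _qlesq_items_from_total(
    totals: np.ndarray, general_item_indices=(15, 16)
) -> np.ndarray:
    """Emit 16 Q-LES-Q items (1-5) whose 14 scored items sum to ``totals``."""
    n = len(totals)
    items = np.full((n, 16), 3, dtype=int)
    scored = [i for i in range(1, 17) if i not in general_item_indices]
    base = totals // 14
    rem = totals - 14 * base
    for pos, idx in enumerate(scored):
        items[:, idx - 1] = base + (pos < rem)
    return items


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate the full cohort from the configured study conditions.

    Week 0 and week 4 visits are drawn from the group's baseline network,
    week 6 from its change-phase network and weeks 9 and 12 from its
    post-change network, so a subject whose maximum change lands at the
    intended week 9 contributes change-network data at their change week.
    Reproducible: the master seed spawns one substream per group.
    """
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    group_seeds = ss.spawn(len(cfg.groups) + 1)
    thr = np.asarray(cfg.thresholds, dtype=float)
    ms_grid, e_grid = _domain_mean_grid(thr)

    def minv(domain_mean):
        return np.interp(domain_mean, e_grid, ms_grid)

    rows: list[pd.DataFrame] = []
    gt_groups = []
    true_nets: dict[tuple[str, str], np.ndarray] = {}
    ones = np.ones(9)

    for g_idx, (g, gss) in enumerate(zip(cfg.groups, group_seeds)):
        rng = np.random.default_rng(gss)
        net_seeds = rng.integers(0, 2**31 - 1, size=3)
        corr = {}
        for phase, s_star, nseed in zip(
            ("baseline", "change", "postchange"),
            (g.strength_baseline, g.strength_change, g.strength_postchange),
            net_seeds,
        ):
            W, R = make_true_network(
                TrueNetworkSpec(
                    target_strength=s_star, density=g.density, seed=int(nseed)
                )
            )
            true_nets[(g.label, phase)] = W
            corr[phase] = R

        # trait variance: largest tau2 keeping every R - tau2*J positive definite
        tau2 = cfg.trait_var_cap
        for R in corr.values():
            bound = 1.0 / float(ones @ np.linalg.solve(R, ones))
            tau2 = min(tau2, 0.8 * bound)
        resid = {ph: R - tau2 * np.outer(ones, ones) for ph, R in corr.items()}

        n = g.n
        trait = rng.normal(0.0, np.sqrt(tau2), size=n)
        delta_i = rng.normal(g.target_delta, g.subject_delta_sd, size=n)
        delta_i = np.clip(delta_i, None, g.baseline_total - 0.5)
        context_good = rng.random(n) < cfg.p_good_context
        female = rng.random(n) < cfg.p_female
        qlesq = np.round(
            np.clip(rng.normal(cfg.qlesq_mean, cfg.qlesq_sd, size=n), 14, 70)
        ).astype(int)
        # keep the emitted class consistent with the latent moderator
        qlesq = np.where(context_good, np.maximum(qlesq, 45), np.minimum(qlesq, 44))

        sids = [f"G{g_idx}S{i:04d}" for i in range(n)]
        base_total = np.full(n, g.baseline_total)
        for week in WEEKS:
            phase = PHASE_OF_WEEK[week]
            if week == 0:
                # baseline: constant group mean plus the subject trait; the
                # trait variance is carved out of R so the cross-sectional
                # correlation matrix is exactly the baseline network's R
                mu = minv(np.full(n, g.baseline_total / 9.0))[:, None] + trait[:, None]
            else:
                frac = np.full(n, cfg.week_fracs[week])
                if week == 12:
                    frac = np.where(
                        context_good,
                        np.minimum(frac * cfg.context_coef, 0.98),
                        frac / cfg.context_coef,
                    )
                # follow-ups anchor to the subject's *realized* baseline
                # total, as clinical change is relative to the patient's own
                # starting severity; the anchored mean spread stands in for
                # the trait (similar variance by construction)
                target_total = np.clip(base_total - frac * delta_i, 0.3, 26.7)
                mu = minv(target_total / 9.0)[:, None]
            dom = sample_ordinal_visit(n, resid[phase], thr, mu, seed=rng)
            if week == 0:
                base_total = dom.sum(axis=1).astype(float)
            items = _qids_items_from_domains(dom, DEFAULT_ITEM_MAP, rng)
            df = pd.DataFrame(
                items, columns=[f"item{i:02d}" for i in range(1, 17)]
            )
            df.insert(0, "week", week)
            df.insert(0, "subject_id", sids)
            df["sex"] = np.where(female, "F", "M")
            if week == 0:
                qi = _qlesq_items_from_total(qlesq)
                for i in range(16):
                    df[f"qlesq{i + 1:02d}"] = qi[:, i]
            rows.append(df)

        gt_groups.append(
            {
                "label": g.label,
                "n": n,
                "target_delta": g.target_delta,
                "baseline_total": g.baseline_total,
                "true_strength": {
                    "baseline": g.strength_baseline,
                    "change": g.strength_change,
                    "postchange": g.strength_postchange,
                },
                "trait_var": float(tau2),
                "subject_prefix": f"G{g_idx}",
            }
        )

    records = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["subject_id", "week"], kind="mergesort")
        .reset_index(drop=True)
    )
    for c in [f"qlesq{i:02d}" for i in range(1, 17)]:
        if c not in records:
            records[c] = np.nan
    ground_truth = {
        "seed": int(master),
        "thresholds": [float(t) for t in thr],
        "context_coef": cfg.context_coef,
        "p_good_context": cfg.p_good_context,
        "week_fracs": {str(k): v for k, v in cfg.week_fracs.items()},
        "groups": gt_groups,
    }
    return SyntheticCohort(
        records=records, ground_truth=ground_truth, true_networks=true_nets
    )
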