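"""End-to-end analysis pipeline.

Runs the full chain on a long-format visit table: scoring -> trajectory
phase assignment and change-magnitude binning -> per-group per-phase network
estimation -> group strength series -> the correlation suite, the
repeated-measures ANOVA of strength over phases, and the responders-vs-
non-responders permutation strength test.  Produces a JSON report plus CSV
tables; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .nct import nct_strength_test
from .network import (
    EstimatorConfig,
    estimate_phase_networks,
    global_strength,
)
from .scoring import (
    DOMAIN_COLS,
    QIDS_ITEM_COLS,
    ScoringError,
    score_visits,
)
from .stats import (
    StatsError,
    paired_t_bonferroni,
    phase_correlation_suite,
    rm_anova_time,
)
from .trajectory import (
    DEFAULT_BIN_EDGES,
    assign_subject_phases,
    bin_groups,
    group_summary,
)

__all__ = ["RunConfig", "AnalysisReport", "read_cohort", "run_full_analysis"]

PHASES = ("baseline", "change", "postchange")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    bin_edges: tuple = DEFAULT_BIN_EDGES
    improvement_only: bool = False
    context_threshold: int | None = None  # None -> sample median (default)
    nct_permutations: int = 1000
    seed: int = 0
    out_dir: str | None = None


@dataclass
class AnalysisReport:
    """All tables and results of one pipeline run."""

    group_table: pd.DataFrame
    strength_series: pd.DataFrame
    correlations: pd.DataFrame
    anova: dict
    paired_tests: pd.DataFrame
    nct: dict | None
    networks: dict
    exclusions: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "group_table": self.group_table.to_dict(orient="records"),
            "strength_series": self.strength_series.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "anova": self.anova,
            "paired_tests": self.paired_tests.to_dict(orient="records"),
            "nct": self.nct,
            "n_networks": len(self.networks),
            "n_excluded": int(len(self.exclusions)),
        }
        return json.dumps(_plain(payload), indent=1, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.group_table.to_csv(out / "group_table.csv", index=False)
        self.strength_series.to_csv(out / "strength_series.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.paired_tests.to_csv(out / "paired_tests.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        nets = out / "networks"
        nets.mkdir(exist_ok=True)
        for (grp, phase), net in self.networks.items():
            tag = f"{grp.strip('[]').replace('-', '_')}_{phase}"
            rows = []
            p = len(net.labels)
            for i in range(p):
                for j in range(i + 1, p):
                    rows.append((net.labels[i], net.labels[j], net.weights[i, j]))
            pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
                nets / f"{tag}.csv", index=False
            )
            sidecar = {
                "group": grp,
                "phase": phase,
                "estimator": net.estimator,
                "n": net.n,
                "strength": global_strength(net),
                "edge_convention": "each unordered pair counted once",
                **{k: _plain(v) for k, v in net.meta.items()},
            }
            (nets / f"{tag}.json").write_text(
                json.dumps(_plain(sidecar), indent=1, sort_keys=True)
            )


def _plain(x):
    if isinstance(x, dict):
        return {str(k): _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def read_cohort(source, dialect: str | None = None) -> pd.DataFrame:
    """Load and validate a long-format cohort table.

    ``source`` is a CSV path or a DataFrame.  The 16-item
    (``item01``..``item16``) and pre-consolidated (``domain1``..``domain9``)
    dialects are auto-detected from the header.  Rows with out-of-range
    values are rejected with their line numbers.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
        if df.empty:
            raise ScoringError(f"{source}: empty file")
    cols = set(df.columns)
    if not {"subject_id", "week"} <= cols:
        raise ScoringError("missing required columns: subject_id, week")
    if dialect is None:
        if set(QIDS_ITEM_COLS) <= cols:
            dialect = "items"
        elif set(DOMAIN_COLS) <= cols:
            dialect = "domains"
        else:
            raise ScoringError(
                "unknown header set: expected item01..item16 or domain1..domain9"
            )
    value_cols = QIDS_ITEM_COLS if dialect == "items" else DOMAIN_COLS
    vals = df[value_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, [0, 1, 2, 3]))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ScoringError(
            f"row {int(r) + 2} (1-based with header): column "
            f"{value_cols[c]} value {vals[r, c]} outside 0-3"
        )
    if not df["week"].isin([0, 4, 6, 9, 12]).all():
        off = sorted(set(df["week"]) - {0, 4, 6, 9, 12})
        raise ScoringError(f"weeks outside the visit schedule: {off}")
    return df


def _strength_series(bins, networks, visits, context) -> pd.DataFrame:
    """One row per group: strengths, mean change and phase severities."""
    ctx = context.set_index("subject_id")["context_class"].to_dict() if len(context) else {}
    base_tot = (
        visits[visits["week"] == 0].set_index("subject_id")["qids_total"].to_dict()
    )
    by_sw = visits.set_index(["subject_id", "week"])["qids_total"].to_dict()
    rows = []
    for b in bins:
        if not all((b.label, ph) in networks for ph in PHASES):
            continue
        row: dict = {"group": b.label, "n": b.n, "mean_delta": b.mean_delta}
        for ph in PHASES:
            net = networks[(b.label, ph)]
            row[f"strength_{ph}"] = global_strength(net)
            sev = []
            for a in b.members:
                wk = {"baseline": 0, "change": a.change_week, "postchange": a.postchange_week}[ph]
                v = by_sw.get((a.subject_id, wk))
                if v is not None and not np.isnan(v):
                    sev.append(v)
            row[f"severity_{ph}"] = float(np.mean(sev)) if sev else np.nan
        w12 = [a.deltas[12] for a in b.members if 12 in a.deltas]
        row["week12_delta"] = float(np.mean(w12)) if w12 else np.nan
        for cls in ("good", "poor"):
            w12c = [
                a.deltas[12]
                for a in b.members
                if 12 in a.deltas and ctx.get(a.subject_id) == cls
            ]
            row[f"week12_delta_{cls}"] = float(np.mean(w12c)) if w12c else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(source, cfg: RunConfig | None = None) -> AnalysisReport:
    """Run the whole pipeline on a cohort table (path or DataFrame)."""
    cfg = cfg or RunConfig()
    records = read_cohort(source)
    scored = score_visits(records, context_threshold=cfg.context_threshold)
    visits, context = scored.visits, scored.context

    assignments, exclusions = assign_subject_phases(visits)
    bins = bin_groups(
        assignments, edges=cfg.bin_edges, improvement_only=cfg.improvement_only
    )
    bins = [b for b in bins if b.n > 0]
    networks = estimate_phase_networks(visits, bins, cfg.estimator)

    series = _strength_series(bins, networks, visits, context)
    correlations = phase_correlation_suite(series)

    anova: dict = {}
    paired = pd.DataFrame()
    strengths = series[[f"strength_{p}" for p in PHASES]].to_numpy()
    if len(series) >= 2:
        try:
            F, df1, df2, p = rm_anova_time(strengths)
            anova = {"F": F, "df1": df1, "df2": df2, "p_value": p}
        except StatsError as e:
            anova = {"error": str(e)}
        paired = paired_t_bonferroni(strengths, labels=list(PHASES))

    # responders vs non-responders at baseline
    nct_result = None
    resp_ids = {a.subject_id for a in assignments if a.responder is True}
    nonresp_ids = {a.subject_id for a in assignments if a.responder is False}
    base = visits[visits["week"] == 0].set_index("subject_id")
    dom_cols = list(scored.item_map.names)
    A = base.loc[base.index.isin(resp_ids), dom_cols].to_numpy(dtype=float)
    B = base.loc[base.index.isin(nonresp_ids), dom_cols].to_numpy(dtype=float)
    if len(A) >= cfg.estimator.min_n and len(B) >= cfg.estimator.min_n:
        try:
            r = nct_strength_test(
                A, B, cfg.estimator, n_perm=cfg.nct_permutations, seed=cfg.seed
            )
            nct_result = {
                "comparison": "responders_vs_nonresponders_baseline",
                "strength_responders": r.strength_a,
                "strength_nonresponders": r.strength_b,
                "observed_diff": r.observed_diff,
                "p_value": r.p_value,
                "n_perm": r.n_perm,
                "n_responders": int(len(A)),
                "n_nonresponders": int(len(B)),
            }
        except RuntimeError as e:
            nct_result = {"error": str(e)}
    else:
        warnings.warn("too few responders/non-responders for the strength test")

    provenance = {
        "software": f"sympnet {__version__}",
        "seed": cfg.seed,
        "estimator": cfg.estimator.estimator,
        "improvement_only": cfg.improvement_only,
        "context_threshold": cfg.context_threshold or "sample_median",
        "n_subjects_included": int(sum(b.n for b in bins)),
        "severity_aggregation": "group mean QIDS total at the phase week",
    }
    sex_map = (
        records.drop_duplicates("subject_id").set_index("subject_id")["sex"].to_dict()
        if "sex" in records.columns
        else None
    )
    report = AnalysisReport(
        group_table=group_summary(bins, visits, sex_by_subject=sex_map),
        strength_series=series,
        correlations=correlations,
        anova=anova,
        paired_tests=paired,
        nct=nct_result,
        networks=networks,
        exclusions=exclusions,
        provenance=provenance,
    )
    if cfg.out_dir is not None:
        report.write(cfg.out_dir)
    return report
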