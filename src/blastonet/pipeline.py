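"""End-to-end orchestration: mesh -> network -> descriptor -> stats -> CV.

A run reads embryos from a directory (one subdirectory of per-cell mesh
files per embryo, plus an ``outcomes.csv``) or generates a synthetic
cohort, then writes descriptor tables, arrangement frequency tables,
group-comparison and cross-validation tables, exported networks, and a
machine-readable manifest.  Embryos failing mesh validation are excluded
and logged with a standardized reason code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import BlastonetError, InvalidInputError, InvalidMeshError
from .meshes import DEFAULT_SCALE_FACTOR, Embryo, contact_network
from .meshio import (
    read_embryo_dir,
    write_network_edge_csv,
    write_network_graphml,
)
from .networks import (
    arrangement_frequencies,
    classify_arrangement_4cell,
    hickman_vector,
    mean_contacts,
)
from .prediction import compare_models, cross_validate
from .stats import gardner_quality, pooled_t_test
from .synthetic import (
    ArrangementSpec,
    LogisticOutcomeModel,
    generate_arrangement,
    sample_gardner_grades,
    simulate_outcomes,
)

logger = logging.getLogger("blastonet")

__all__ = [
    "RunConfig",
    "parse_config",
    "generate_cohort",
    "run_pipeline",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = ("UNREADABLE_MESH", "DEGENERATE_MESH", "WRONG_CELL_COUNT")

#: default synthetic cohort: counts per arrangement
DEFAULT_COHORT = {
    "pseudotetrahedral": 16,
    "tetrahedral": 14,
    "planar": 12,
    "closed_y": 10,
    "linear": 8,
}

_OUTCOME_COLUMNS = (
    "blastulated",
    "transferred",
    "biochemical_pregnancy",
    "live_birth",
    "miscarriage",
    "euploid",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str | None = None  # read embryos from here when set
    cohort: dict = field(default_factory=lambda: dict(DEFAULT_COHORT))
    n_packed_8cell: int = 0
    jitter_sd: float = 0.0
    mesh_subdivisions: int = 2
    scale_factor: float = DEFAULT_SCALE_FACTOR
    stage: str = "both"  # t4 | t8 | both
    comparisons: tuple = ("blastulated", "quality", "biochemical_pregnancy", "live_birth")
    cv_outcomes: tuple = ("biochemical_pregnancy", "live_birth")
    cv_folds: int = 5
    out_dir: str = "blastonet_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (1.0 < self.scale_factor <= 1.5):
            logger.warning(
                "scale_factor %.3f outside the validated range (1, 1.5]",
                self.scale_factor,
            )
        if self.stage not in ("t4", "t8", "both"):
            raise InvalidInputError(f"stage must be t4|t8|both, got {self.stage!r}")


def parse_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidInputError(f"bad config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "cohort":
            cohort = {}
            for item in value.split(","):
                name, count = item.split(":")
                cohort[name.strip()] = int(count)
            kwargs["cohort"] = cohort
        elif key in ("comparisons", "cv_outcomes"):
            kwargs[key] = tuple(s.strip() for s in value.split(","))
        elif key in ("n_packed_8cell", "cv_folds", "seed", "mesh_subdivisions"):
            kwargs[key] = int(value)
        elif key in ("jitter_sd", "scale_factor"):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------


def generate_cohort(config: RunConfig) -> tuple[list[Embryo], pd.DataFrame]:
    """Generate embryos plus a simulated outcomes table.

    Outcome labels are drawn from logistic models of each embryo's
    ground-truth mean-contacts value, encoding the premise that more
    contact goes with better outcomes.
    """
    embryos: list[Embryo] = []
    idx = 0
    for name, count in config.cohort.items():
        for _ in range(count):
            spec = ArrangementSpec(
                name=name,
                n_cells=4,
                jitter_sd=config.jitter_sd,
                mesh_subdivisions=config.mesh_subdivisions,
                seed=config.seed * 100003 + idx,
            )
            emb = generate_arrangement(spec)
            embryos.append(
                Embryo(embryo_id=f"emb{idx:04d}_{name}", blastomeres=emb.blastomeres)
            )
            idx += 1
    for _ in range(config.n_packed_8cell):
        spec = ArrangementSpec(
            name="packed_n8",
            n_cells=8,
            jitter_sd=config.jitter_sd,
            mesh_subdivisions=config.mesh_subdivisions,
            seed=config.seed * 100003 + idx,
        )
        emb = generate_arrangement(spec)
        embryos.append(
            Embryo(embryo_id=f"emb{idx:04d}_packed_n8", blastomeres=emb.blastomeres)
        )
        idx += 1

    # simulate outcomes from ground-truth mean contacts
    mc = np.array(
        [
            mean_contacts(contact_network(e, config.scale_factor))
            for e in embryos
        ]
    )
    n = len(embryos)
    rng_seed = config.seed + 17
    rows: dict = {"embryo_id": [e.embryo_id for e in embryos]}
    rows["stage"] = [e.stage for e in embryos]
    centered = mc - mc.mean() if n else mc
    _, blast = simulate_outcomes(
        LogisticOutcomeModel(intercept=1.0, slope=1.2), centered, seed=rng_seed
    )
    rows["blastulated"] = blast.astype(bool)
    rows["gardner"] = sample_gardner_grades(n, p_good=0.55, seed=rng_seed + 1)
    transferred = np.random.default_rng(rng_seed + 2).random(n) < 0.6
    rows["transferred"] = transferred
    _, preg = simulate_outcomes(
        LogisticOutcomeModel(intercept=0.3, slope=1.0), centered, seed=rng_seed + 3
    )
    preg = np.where(transferred, preg, -1)
    rows["biochemical_pregnancy"] = preg
    _, birth = simulate_outcomes(
        LogisticOutcomeModel(intercept=0.0, slope=1.0), centered, seed=rng_seed + 4
    )
    birth = np.where(transferred & (preg == 1), birth, np.where(transferred, 0, -1))
    rows["live_birth"] = birth
    rows["miscarriage"] = np.where(
        transferred, (preg == 1) & (birth == 0), -1
    ).astype(int)
    _, eup = simulate_outcomes(
        LogisticOutcomeModel(intercept=0.8, slope=0.3), centered, seed=rng_seed + 5
    )
    rows["euploid"] = eup
    return embryos, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def load_embryos(input_dir: str | Path) -> tuple[list[Embryo], pd.DataFrame | None, list]:
    """Read embryo subdirectories; returns (embryos, outcomes table or None,
    exclusion records)."""
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise InvalidInputError(f"input directory not found: {input_dir}")
    subdirs = sorted(p for p in input_dir.iterdir() if p.is_dir())
    if not subdirs:
        raise InvalidInputError(f"no embryo subdirectories in {input_dir}")
    embryos, excluded = [], []
    for sub in subdirs:
        try:
            emb = read_embryo_dir(sub)
            for m in emb.blastomeres:
                m.validate()
        except InvalidMeshError as exc:
            reason = "DEGENERATE_MESH" if "degenerate" in str(exc) else "UNREADABLE_MESH"
            excluded.append({"embryo_id": sub.name, "reason": reason, "detail": str(exc)})
            logger.info("excluded %s: %s (%s)", sub.name, reason, exc)
            continue
        embryos.append(emb)
    outcomes_path = input_dir / "outcomes.csv"
    outcomes = pd.read_csv(outcomes_path) if outcomes_path.exists() else None
    return embryos, outcomes, excluded


def describe_embryos(
    embryos: list[Embryo], scale_factor: float = DEFAULT_SCALE_FACTOR
) -> tuple[pd.DataFrame, dict]:
    """Per-embryo descriptor table and the contact networks keyed by id."""
    records, networks = [], {}
    for emb in embryos:
        net = contact_network(emb, scale_factor)
        networks[emb.embryo_id] = net
        hv = hickman_vector(net)
        label = classify_arrangement_4cell(hv) if emb.stage == 4 else ""
        records.append(
            {
                "embryo_id": emb.embryo_id,
                "stage": emb.stage,
                "hickman_vector": json.dumps(list(hv)),
                "mean_contacts": mean_contacts(net),
                "arrangement_label": label,
            }
        )
    return pd.DataFrame(records), networks


def stats_table(descriptors: pd.DataFrame, outcomes: pd.DataFrame, comparisons) -> pd.DataFrame:
    """Table of group comparisons of mean_contacts per stage and outcome.

    Pregnancy/live-birth/miscarriage comparisons include transferred
    embryos only.
    """
    df = descriptors.merge(outcomes, on="embryo_id", suffixes=("", "_meta"))
    if "quality" not in df.columns and "gardner" in df.columns:
        df["quality"] = [
            gardner_quality(g) if isinstance(g, str) and g else None
            for g in df["gardner"]
        ]
    rows = []
    stage_col = "stage" if "stage" in descriptors.columns else "stage_meta"
    for stage in sorted(df[stage_col].unique()):
        sub = df[df[stage_col] == stage]
        for comp in comparisons:
            if comp not in sub.columns:
                continue
            part = sub
            if comp in ("biochemical_pregnancy", "live_birth", "miscarriage"):
                part = sub[sub["transferred"].astype(bool)]
            col = part[comp]
            if comp == "quality":
                pos = part[col == "good"]["mean_contacts"].to_numpy()
                neg = part[col == "poor"]["mean_contacts"].to_numpy()
            else:
                valid = part[col.isin((0, 1, True, False))]
                pos = valid[valid[comp].astype(int) == 1]["mean_contacts"].to_numpy()
                neg = valid[valid[comp].astype(int) == 0]["mean_contacts"].to_numpy()
            if len(pos) < 2 or len(neg) < 2:
                continue
            res = pooled_t_test(pos, neg)
            rows.append(
                {
                    "stage": f"t{stage}",
                    "comparison": comp,
                    "group1_mean": np.mean(pos),
                    "group1_sd": np.std(pos, ddof=1),
                    "group1_n": len(pos),
                    "group2_mean": np.mean(neg),
                    "group2_sd": np.std(neg, ddof=1),
                    "group2_n": len(neg),
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def cv_table(
    descriptors: pd.DataFrame,
    outcomes: pd.DataFrame,
    cv_outcomes,
    feature: str = "mean_contacts",
    comparator_feature: str | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Cross-validated threshold-classifier metrics for each outcome, with
    an optional rival feature compared by unpaired t-test on fold AUCs."""
    df = descriptors.merge(outcomes, on="embryo_id", suffixes=("", "_meta"))
    rows, detail = [], {}
    for outcome in cv_outcomes:
        if outcome not in df.columns:
            continue
        part = df
        if outcome in ("biochemical_pregnancy", "live_birth", "miscarriage"):
            part = df[df["transferred"].astype(bool)]
        part = part[part[outcome].isin((0, 1, True, False))]
        y = part[outcome].astype(int).to_numpy()
        if len(y) < k or y.min() == y.max():
            continue
        if min(int((y == 0).sum()), int((y == 1).sum())) < k:
            logger.info("skipping CV for %s: minority class smaller than k", outcome)
            continue
        features = [feature] + ([comparator_feature] if comparator_feature else [])
        reports = {}
        for feat in features:
            rep = cross_validate(
                part[feat].to_numpy(dtype=float),
                y,
                k=k,
                seed=seed,
                feature_name=feat,
                outcome_name=outcome,
            )
            reports[feat] = rep
            for metric, (mean, sd) in rep.summary.items():
                rows.append(
                    {
                        "outcome": outcome,
                        "feature": feat,
                        "metric": metric,
                        "mean": mean,
                        "sd": sd,
                    }
                )
            rows.append(
                {
                    "outcome": outcome,
                    "feature": feat,
                    "metric": "threshold",
                    "mean": rep.theta_mean,
                    "sd": rep.theta_sd,
                }
            )
        entry = {
            feat: {
                "theta_mean": rep.theta_mean,
                "theta_sd": rep.theta_sd,
                "summary": rep.summary,
                "fold_aucs": rep.fold_aucs,
            }
            for feat, rep in reports.items()
        }
        if comparator_feature and len(reports) == 2:
            cmp = compare_models(reports[feature], reports[comparator_feature])
            entry["auc_comparison"] = {
                "t_statistic": cmp.t_statistic,
                "p_value": cmp.p_value,
            }
        detail[outcome] = entry
    return pd.DataFrame(rows), detail


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    try:
        excluded: list = []
        if config.input_dir:
            embryos, outcomes, excluded = load_embryos(config.input_dir)
        else:
            embryos, outcomes = generate_cohort(config)

        if config.stage != "both":
            want = 4 if config.stage == "t4" else 8
            kept = [e for e in embryos if e.stage == want]
            for e in embryos:
                if e.stage != want:
                    excluded.append(
                        {
                            "embryo_id": e.embryo_id,
                            "reason": "WRONG_CELL_COUNT",
                            "detail": f"stage {e.stage} != {want}",
                        }
                    )
            embryos = kept
        if not embryos:
            raise InvalidInputError("no embryos to analyse after filtering")

        descriptors, networks = describe_embryos(embryos, config.scale_factor)
        descriptors.to_csv(out / "descriptors.csv", index=False)

        nets_dir = out / "networks"
        nets_dir.mkdir(exist_ok=True)
        for emb_id, net in networks.items():
            write_network_graphml(net, nets_dir / f"{emb_id}.graphml")
            write_network_edge_csv(net, nets_dir / f"{emb_id}.edges.csv")

        for stage in sorted(descriptors["stage"].unique()):
            ids = descriptors[descriptors["stage"] == stage]["embryo_id"]
            freq = arrangement_frequencies([networks[i] for i in ids])
            freq.to_csv(out / f"frequencies_t{stage}.csv", index=False)

        artifacts = {
            "descriptors": "descriptors.csv",
            "networks_dir": "networks",
        }
        if outcomes is not None:
            outcomes.to_csv(out / "outcomes.csv", index=False)
            table2 = stats_table(descriptors, outcomes, config.comparisons)
            table2.to_csv(out / "group_comparisons.csv", index=False)
            table4, detail = cv_table(
                descriptors,
                outcomes,
                config.cv_outcomes,
                k=config.cv_folds,
                seed=config.seed,
            )
            table4.to_csv(out / "cv_metrics.csv", index=False)
            (out / "cv_detail.json").write_text(json.dumps(detail, indent=2))
            artifacts.update(
                {
                    "group_comparisons": "group_comparisons.csv",
                    "cv_metrics": "cv_metrics.csv",
                    "cv_detail": "cv_detail.json",
                }
            )

        pd.DataFrame(
            excluded, columns=["embryo_id", "reason", "detail"]
        ).to_csv(out / "exclusions.csv", index=False)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "scale_factor": config.scale_factor,
            "stage": config.stage,
            "n_embryos": len(embryos),
            "n_excluded": len(excluded),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            },
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if failed_marker.exists():
            failed_marker.unlink()
        return manifest
    except BlastonetError as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
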