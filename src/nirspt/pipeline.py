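"""End-to-end study orchestration: simulate -> code -> preprocess -> GLM ->
group statistics, with deterministic seeding and table-shaped reports.

``run_study`` executes the full chain on a synthetic cohort and returns a
:class:`StudyReport` whose tables mirror the layout a perspective-taking
fNIRS study reports: subgroup descriptives, ROI activation means by group
and subgroup, t-test and ANOVA summaries, RT analyses, the trial-level
log-RT mixed model for the inconsistent subgroups, and PFT-activation
correlations.  Identical config + seed produces byte-identical report
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import stats as st
from .glm import aggregate_roi, build_regressor, canonical_hrf, fit_glm_session
from .montage import ROI_LABELS, build_montage, default_roi_map, roi_map_from_yaml
from .preprocess import PreprocessConfig, preprocess_session
from .simulate import (
    STUDY_SUBGROUP_SIZES,
    SUBGROUPS,
    BehaviorPolicy,
    NoiseModel,
    default_planted_activation,
    default_policies,
    simulate_cohort,
)

FLOAT_FMT = "%.6f"


@dataclass
class StudyConfig:
    """Everything a full study run depends on."""

    subgroup_sizes: tuple[int, int, int, int] = STUDY_SUBGROUP_SIZES
    seed: int = 0
    between_subject_sd: float = 0.75
    include_optical: bool = True
    hbr_ratio: float = 0.5
    noise: NoiseModel = field(default_factory=NoiseModel)
    policies: dict[str, BehaviorPolicy] = field(default_factory=default_policies)
    planted: dict = field(default_factory=default_planted_activation)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    roi_map_path: str | None = None  # YAML; None -> packaged synthetic map

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a config; unspecified fields keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "subgroup_sizes" in raw:
            kwargs["subgroup_sizes"] = tuple(int(x) for x in raw["subgroup_sizes"])
        for key in ("seed", "between_subject_sd", "include_optical", "hbr_ratio",
                    "roi_map_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "noise" in raw:
            kwargs["noise"] = NoiseModel(**raw["noise"])
        if "policies" in raw:
            policies = default_policies()
            policies.update(
                {sg: BehaviorPolicy(**p) for sg, p in raw["policies"].items()}
            )
            kwargs["policies"] = policies
        if "planted" in raw:
            kwargs["planted"] = raw["planted"]
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
        return cls(**kwargs)


@dataclass
class StudyReport:
    """All output tables of one study run, plus provenance metadata."""

    participant_table: pd.DataFrame
    subgroup_descriptives: pd.DataFrame
    roi_activation: pd.DataFrame  # participant x ROI betas + labels
    roi_by_group: pd.DataFrame  # mean (sd) per ROI x group
    roi_by_subgroup: pd.DataFrame
    ttests_by_group: pd.DataFrame
    rt_by_group: pd.DataFrame
    anova_table: pd.DataFrame
    rt_anova: pd.DataFrame
    posthoc_left_ifg: pd.DataFrame
    lmm_summary: dict
    correlations: pd.DataFrame
    elimination: dict
    exclusion_log: pd.DataFrame
    metadata: dict


def _mean_sd(frame: pd.DataFrame, by: str, cols) -> pd.DataFrame:
    gp = frame.groupby(by)
    out = {}
    for label, sub in gp:
        for c in cols:
            out.setdefault(c, {})[f"{label}_mean"] = sub[c].mean()
            out.setdefault(c, {})[f"{label}_sd"] = sub[c].std(ddof=1)
    return pd.DataFrame(out).T.rename_axis("ROI")


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Execute the full pipeline for one cohort."""
    cfg = config or StudyConfig()
    montage = build_montage()
    roi_map = (
        roi_map_from_yaml(cfg.roi_map_path)
        if cfg.roi_map_path
        else default_roi_map()
    )
    cohort = simulate_cohort(
        subgroup_sizes=cfg.subgroup_sizes,
        policies=cfg.policies,
        planted=cfg.planted,
        noise=cfg.noise,
        seed=cfg.seed,
        between_subject_sd=cfg.between_subject_sd,
        include_optical=cfg.include_optical,
        montage=montage,
        roi_map=roi_map,
        hbr_ratio=cfg.hbr_ratio,
    )

    records = []
    roi_rows: dict[str, dict[str, float]] = {}
    exclusions = []
    hrf = canonical_hrf()
    for part in cohort:
        try:
            rec = beh.build_participant_record(
                part.participant_id, part.trials, part.responses, part.covariates
            )
        except Exception as exc:
            raise RuntimeError(
                f"behavioral coding failed for {part.participant_id}: {exc}"
            ) from exc
        records.append(rec)
        if part.optical is None:
            continue
        try:
            merged, report = preprocess_session(part.optical, cfg.preprocess)
        except Exception as exc:
            raise RuntimeError(
                f"preprocessing failed for {part.participant_id}: {exc}"
            ) from exc
        exclusions.append(
            {"participant_id": part.participant_id, **report.to_dict()}
        )
        if report.excluded:
            continue
        regressor = build_regressor(
            part.timeline.stimulus_onset_s, hrf, merged.signal.shape[1]
        )
        glm = fit_glm_session(merged.signal, regressor, montage.channel_ids)
        roi_rows[part.participant_id] = aggregate_roi(glm, roi_map)

    part_table = beh.participants_frame(records)
    rois_present = [r for r in ROI_LABELS if r in roi_map]

    # --- behavioral / demographic tables -------------------------------
    desc_rows = []
    for sg in SUBGROUPS:
        sub = part_table[part_table["subgroup"] == sg]
        desc_rows.append(
            {
                "subgroup": sg,
                "n": len(sub),
                "n_female": int((sub["sex"] == "female").sum()),
                "n_male": int((sub["sex"] == "male").sum()),
                "age_mean": sub["age"].mean(),
                "age_sd": sub["age"].std(ddof=1),
                "pft_mean": sub["pft_score"].mean(),
                "pft_sd": sub["pft_score"].std(ddof=1),
                "rt_mean_ms": sub["mean_rt_ms"].mean(),
                "rt_sd_ms": sub["mean_rt_ms"].std(ddof=1),
            }
        )
    descriptives = pd.DataFrame(desc_rows)

    elim = beh.elimination_table(records)
    try:
        elim_chi = st.chisq_2x2(elim.values)
        elimination = {
            "table": {g: list(map(int, elim.loc[g])) for g in elim.index},
            "chi_sq": elim_chi.chi_sq,
            "df": elim_chi.df,
            "p": elim_chi.p,
        }
    except ValueError as exc:
        elimination = {
            "table": {g: list(map(int, elim.loc[g])) for g in elim.index},
            "note": f"chi-square not computed: {exc}",
        }

    rt_by_group = part_table.groupby("group")["mean_rt_ms"].agg(
        ["count", "mean", "std"]
    )
    rt_rows = {"groups": rt_by_group.reset_index()}
    ego_rt = part_table.loc[part_table["group"] == "egocentric", "mean_rt_ms"]
    alt_rt = part_table.loc[part_table["group"] == "altercentric", "mean_rt_ms"]
    if len(ego_rt) >= 2 and len(alt_rt) >= 2:
        res = st.independent_t(alt_rt, ego_rt)
        rt_rows["t"] = res.t
        rt_rows["p"] = res.p
        rt_rows["d"] = res.cohens_d
    rt_group_table = rt_by_group.reset_index().rename(
        columns={"count": "n", "mean": "rt_mean_ms", "std": "rt_sd_ms"}
    )
    for k in ("t", "p", "d"):
        rt_group_table[k] = rt_rows.get(k, np.nan)

    # --- ROI activation tables -----------------------------------------
    roi_act = pd.DataFrame.from_dict(roi_rows, orient="index")
    roi_act.index.name = "participant_id"
    labels = part_table.set_index("participant_id")
    if len(roi_act):
        roi_act = roi_act.join(labels[["group", "subgroup", "pft_score"]])

    def placeholder(reason: str) -> pd.DataFrame:
        return pd.DataFrame({"note": [f"not computed: {reason}"]})

    if len(roi_act):
        roi_by_group = _mean_sd(roi_act, "group", rois_present)
        roi_by_subgroup = _mean_sd(roi_act, "subgroup", rois_present)

        tt_rows = []
        for roi in rois_present:
            ego = roi_act.loc[roi_act["group"] == "egocentric", roi]
            alt = roi_act.loc[roi_act["group"] == "altercentric", roi]
            if len(ego) >= 2 and len(alt) >= 2:
                res = st.independent_t(ego, alt)
                tt_rows.append(
                    {
                        "ROI": roi,
                        "t": res.t,
                        "p": res.p,
                        "d": res.cohens_d,
                        "ci_low": res.ci_95[0],
                        "ci_high": res.ci_95[1],
                    }
                )
        ttests = pd.DataFrame(tt_rows)

        an_rows = []
        persp = roi_act["subgroup"].str.split("-").str[0]
        cons = roi_act["subgroup"].str.split("-").str[1]
        four_cells = persp.nunique() == 2 and cons.nunique() == 2 and (
            pd.crosstab(persp, cons).values > 0
        ).all()
        if four_cells:
            for roi in rois_present:
                res = st.anova_2x2_type3(roi_act[roi], persp, cons)
                for name, eff in res.effects().items():
                    an_rows.append(
                        {
                            "ROI": roi,
                            "effect": name,
                            "F": eff.F,
                            "MSE": eff.ms_error,
                            "df1": eff.df[0],
                            "df2": eff.df[1],
                            "p": eff.p,
                            "partial_eta_sq": eff.partial_eta_sq,
                        }
                    )
            anova_table = pd.DataFrame(an_rows)
            rt_an = st.anova_2x2_type3(
                part_table["mean_rt_ms"],
                part_table["subgroup"].str.split("-").str[0],
                part_table["subgroup"].str.split("-").str[1],
            )
            rt_anova = pd.DataFrame(
                [
                    {
                        "effect": name,
                        "F": eff.F,
                        "MSE": eff.ms_error,
                        "df1": eff.df[0],
                        "df2": eff.df[1],
                        "p": eff.p,
                        "partial_eta_sq": eff.partial_eta_sq,
                    }
                    for name, eff in rt_an.effects().items()
                ]
            )
            focus_roi = "left_IFG" if "left_IFG" in rois_present else rois_present[0]
            posthoc = st.posthoc_pairwise(
                roi_act[focus_roi], roi_act["subgroup"], correction="none"
            )
        else:
            anova_table = placeholder("a perspective x consistency cell is empty")
            rt_anova = placeholder("a perspective x consistency cell is empty")
            posthoc = placeholder("a perspective x consistency cell is empty")

        corr_rows = []
        for roi in rois_present:
            try:
                res = st.pearson_corr(roi_act["pft_score"], roi_act[roi])
                corr_rows.append({"ROI": roi, "r": res.r, "p": res.p, "n": res.n})
            except ValueError:
                pass
        correlations = (
            pd.DataFrame(corr_rows) if corr_rows else placeholder("degenerate PFT")
        )
    else:
        reason = "no optical data (behavior-only run)"
        roi_by_group = placeholder(reason)
        roi_by_subgroup = placeholder(reason)
        ttests = placeholder(reason)
        anova_table = placeholder(reason)
        rt_anova = placeholder(reason)
        posthoc = placeholder(reason)
        correlations = placeholder(reason)

    # --- trial-level LMM on the inconsistent subgroups ------------------
    trial_table = beh.trials_frame(records)
    incon = trial_table[trial_table["subgroup"].str.endswith("inconsistent")]
    incon = incon[incon["retained"]]
    lmm_summary: dict
    if (
        incon["subgroup"].nunique() == 2
        and incon.groupby("subgroup")["participant_id"].nunique().min() >= 2
        and incon["perspective"].nunique() == 2
    ):
        lmm_input = pd.DataFrame(
            {
                "subject": incon["participant_id"],
                "trial": incon["trial_index"],
                "group": incon["subgroup"],
                "response": incon["perspective"],
                "rt": incon["rt_ms"],
            }
        )
        try:
            lmm = st.fit_rt_lmm(lmm_input)
            lmm_summary = {
                "fixed_effects": {
                    term: {
                        "estimate": float(row["estimate"]),
                        "t": float(row["t"]),
                        "p": float(row["p"]),
                    }
                    for term, row in lmm.fixed_effects.iterrows()
                },
                "variance_components": lmm.variance_components,
                "r2_marginal": lmm.r2_marginal,
                "r2_conditional": lmm.r2_conditional,
                "posthoc": lmm.posthoc.to_dict(orient="records"),
                "converged": lmm.converged,
            }
        except Exception as exc:
            lmm_summary = {"note": f"not computed: {exc}"}
    else:
        lmm_summary = {"note": "not computed: too few inconsistent participants"}

    metadata = {
        "package": "nirspt",
        "seed": int(cfg.seed),
        "subgroup_sizes": [int(s) for s in cfg.subgroup_sizes],
        "n_participants": int(len(records)),
        "n_analyzed_fnirs": int(len(roi_rows)),
        "between_subject_sd": float(cfg.between_subject_sd),
    }

    return StudyReport(
        participant_table=part_table,
        subgroup_descriptives=descriptives,
        roi_activation=roi_act if len(roi_act) else placeholder("no optical data"),
        roi_by_group=roi_by_group,
        roi_by_subgroup=roi_by_subgroup,
        ttests_by_group=ttests,
        rt_by_group=rt_group_table,
        anova_table=anova_table,
        rt_anova=rt_anova,
        posthoc_left_ifg=posthoc,
        lmm_summary=lmm_summary,
        correlations=correlations,
        elimination=elimination,
        exclusion_log=pd.DataFrame(exclusions),
        metadata=metadata,
    )


_TABLE_FIELDS = [
    "participant_table",
    "subgroup_descriptives",
    "roi_activation",
    "roi_by_group",
    "roi_by_subgroup",
    "ttests_by_group",
    "rt_by_group",
    "anova_table",
    "rt_anova",
    "posthoc_left_ifg",
    "correlations",
    "exclusion_log",
]


def write_report(report: StudyReport, out_dir, fmt: str = "tsv") -> list[Path]:
    """Write every report table to ``out_dir``.

    ``fmt`` is "tsv" or "json"; floats are printed at fixed precision so
    identical runs produce byte-identical files.  A metadata JSON with
    the seed and version is always written.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _TABLE_FIELDS:
        frame: pd.DataFrame = getattr(report, name)
        if fmt == "tsv":
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=True)
        else:
            path = out / f"{name}.json"
            rounded = frame.reset_index().copy()
            for c in rounded.columns:
                if rounded[c].dtype.kind == "f":
                    rounded[c] = rounded[c].round(6)
            path.write_text(
                json.dumps(rounded.to_dict(orient="records"), indent=1, sort_keys=True,
                           default=str)
            )
        written.append(path)
    for name, payload in (
        ("lmm_summary", report.lmm_summary),
        ("elimination", report.elimination),
        ("metadata", report.metadata),
    ):
        path = out / f"{name}.json"
        path.write_text(json.dumps(_round_floats(payload), indent=1, sort_keys=True))
        written.append(path)
    return written


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj
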