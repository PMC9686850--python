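"""End-to-end orchestration: simulate -> extract -> preprocess -> screen ->
train/evaluate, with per-stage artifacts, derived seeds and resumability.

A single :class:`PipelineConfig` fully determines a run; each stage derives
its own seed deterministically from the global one, so reruns with the same
config are identical. Stages write their outputs under ``out_dir`` and are
skipped when those outputs already exist (unless forced).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import fit_logistic, univariate_table
from .cohort import CohortSpec, generate_cohort
from .evaluation import SplitScheme, delong_ci, run_experiment
from .features import FeatureBankConfig, extract_all
from .gbdt import GradientBoostingBernoulli
from .preprocess import Smote, drop_null_features, encode_clinical, impute_clinical
from .roi import RoiConfig, build_all_rois
from .screening import ScreeningCascade, clinical_prescreen

__all__ = ["PipelineConfig", "run_all", "report_summary", "stage_seed"]

STAGES = ("simulate", "extract", "preprocess", "screen", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    roi: RoiConfig = field(default_factory=RoiConfig)
    bank: FeatureBankConfig = field(default_factory=FeatureBankConfig)
    smote_k: int = 5
    smote_ratio: float = 1.0
    screening: dict = field(default_factory=dict)
    gbdt: dict = field(default_factory=dict)
    scheme: SplitScheme = field(default_factory=SplitScheme)
    clinical_alpha: float = 0.5
    seed: int = 0
    leakage_safe: bool = False
    out_dir: str = "dermrad_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortSpec(**raw["cohort"])
        if "roi" in raw:
            kwargs["roi"] = RoiConfig(**raw["roi"])
        if "bank" in raw:
            kwargs["bank"] = FeatureBankConfig(**raw["bank"])
        if "scheme" in raw:
            kwargs["scheme"] = SplitScheme(**raw["scheme"])
        for key in ("smote_k", "smote_ratio", "screening", "gbdt", "clinical_alpha",
                    "seed", "leakage_safe", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _simulate(cfg: PipelineConfig):
    spec = cfg.cohort
    spec.seed = stage_seed(cfg.seed, "simulate")
    return generate_cohort(spec)


def _extract(cfg: PipelineConfig, patients) -> pd.DataFrame:
    rows = []
    for p in patients:
        rois = build_all_rois(p.dose, p.ptv_mask, p.skin_mask, cfg.roi, image=p.image)
        rows.append(extract_all(p.image, rois, cfg.bank))
    return pd.DataFrame(rows, index=[p.patient_id for p in patients])


def run_all(cfg: PipelineConfig, force: bool = False,
            stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline in order, writing artifacts under ``cfg.out_dir``.

    Returns a dict with the main in-memory results (tables, reports).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- simulate + extract ------------------------------------------------
    feat_path = out / "features.csv"
    clin_path = out / "clinical.csv"
    if force or not feat_path.exists() or not clin_path.exists() or "simulate" in stages and force:
        patients = _simulate(cfg)
        clinical = pd.DataFrame([p.clinical for p in patients],
                                index=[p.patient_id for p in patients])
        clinical["RD2plus"] = [p.label for p in patients]
        clinical.to_csv(clin_path)
        features = _extract(cfg, patients)
        features.to_csv(feat_path)
    else:
        clinical = pd.read_csv(clin_path, index_col=0)
        features = pd.read_csv(feat_path, index_col=0)
    labels = clinical["RD2plus"].to_numpy(int)
    clinical = clinical.drop(columns=["RD2plus"])
    results["features"] = features
    results["clinical"] = clinical
    results["labels"] = labels

    # ---- preprocess --------------------------------------------------------
    if clinical.isna().any().any():
        clinical = impute_clinical(clinical, seed=stage_seed(cfg.seed, "impute"))
    features_kept, retention = drop_null_features(features)
    (out / "retention.json").write_text(json.dumps(retention, indent=1))
    results["retention"] = retention

    uni = univariate_table(clinical, labels, seed=stage_seed(cfg.seed, "univariate"))
    uni_df = pd.DataFrame([{"variable": u.variable, "test": u.test,
                            "statistic": u.statistic, "p": u.p_value} for u in uni])
    uni_df.to_csv(out / "clinical_univariate.csv", index=False)
    pvals = pd.Series(uni_df["p"].to_numpy(), index=uni_df["variable"])
    selected_clin = clinical_prescreen(pvals, cfg.clinical_alpha)
    results["clinical_selected"] = selected_clin

    clin_enc = encode_clinical(clinical)
    if selected_clin:
        logit = fit_logistic(clin_enc[selected_clin], labels)
        logit.summary().to_csv(out / "clinical_logistic.csv")
        results["logistic"] = logit
    else:
        results["logistic"] = None

    cat_cols = [c for c in clin_enc.columns
                if not pd.api.types.is_numeric_dtype(clinical[c])]
    combined = pd.concat([clin_enc, features_kept], axis=1)
    smote_seed = stage_seed(cfg.seed, "smote")
    if not cfg.leakage_safe:
        sampler = Smote(cfg.smote_k, cfg.smote_ratio,
                        tuple(combined.columns.get_loc(c) for c in cat_cols),
                        random_state=smote_seed)
        Xb, yb = sampler.fit_resample(combined.to_numpy(float), labels)
        balanced = pd.DataFrame(Xb, columns=combined.columns)
        y_model = yb
    else:
        balanced = combined.reset_index(drop=True)
        y_model = labels
    results["balanced_n"] = int(len(balanced))
    bal_clin = balanced[clin_enc.columns]
    bal_feat = balanced[features_kept.columns]

    # ---- screen ------------------------------------------------------------
    scheme = SplitScheme(**{**asdict(cfg.scheme),
                            "seed": stage_seed(cfg.seed, "split")})
    if cfg.leakage_safe:
        reports, per_split_selected = _nested_evaluation(
            features_kept, clin_enc, clinical, labels, cfg, scheme,
            smote_seed, cat_cols)
        results["screening"] = None
        results["radiomics_selected"] = per_split_selected
        (out / "screening.json").write_text(
            json.dumps({"per_split_selected": per_split_selected}, indent=1))
    else:
        cascade = ScreeningCascade(random_state=stage_seed(cfg.seed, "screen"),
                                   **cfg.screening)
        cascade.fit(bal_feat, y_model)
        (out / "screening.json").write_text(
            json.dumps(cascade.report_.to_dict(), indent=1))
        results["screening"] = cascade.report_
        selected_feat = cascade.selected_
        results["radiomics_selected"] = selected_feat

        # ---- train + evaluate ---------------------------------------------
        reports = {}
        clin_sel_df = bal_clin[selected_clin] if selected_clin else bal_clin
        feat_sel_df = bal_feat[selected_feat]
        for kind in ("clinical", "radiomics", "combined"):
            reports[kind] = run_experiment(feat_sel_df, clin_sel_df, y_model, kind,
                                           gbdt_params=cfg.gbdt, scheme=scheme)
    (out / "eval_report.json").write_text(
        json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=1)
    )
    results["reports"] = reports
    return results


def _nested_evaluation(features, clin_enc, clin_raw, labels, cfg, scheme,
                       smote_seed, cat_cols):
    """Leakage-safe evaluation: every supervised step (clinical pre-screen,
    SMOTE, the screening cascade) is refitted inside each training split;
    validation rows are untouched originals the selection never saw."""
    from .evaluation import EvalReport, ModelResult, make_splits

    y = np.asarray(labels)
    reports = {kind: EvalReport(kind=kind, feature_names=[])
               for kind in ("clinical", "radiomics", "combined")}
    per_split_selected = []
    for k, (tr, va) in enumerate(make_splits(y, scheme)):
        uni = univariate_table(clin_raw.iloc[tr], y[tr],
                               seed=stage_seed(cfg.seed, f"uni{k}"))
        pvals = pd.Series({u.variable: u.p_value for u in uni})
        sel_clin = clinical_prescreen(pvals, cfg.clinical_alpha) or list(clin_enc.columns)

        combined = pd.concat([clin_enc, features], axis=1)
        cat_idx = tuple(combined.columns.get_loc(c) for c in cat_cols)
        sampler = Smote(cfg.smote_k, cfg.smote_ratio, cat_idx,
                        random_state=smote_seed + k)
        Xb, yb = sampler.fit_resample(combined.iloc[tr].to_numpy(float), y[tr])
        balanced = pd.DataFrame(Xb, columns=combined.columns)

        cascade = ScreeningCascade(random_state=stage_seed(cfg.seed, f"screen{k}"),
                                   **cfg.screening)
        cascade.fit(balanced[features.columns], yb)
        sel_feat = cascade.selected_
        per_split_selected.append(sel_feat)

        tables = {
            "clinical": (balanced[sel_clin], clin_enc[sel_clin].iloc[va]),
            "radiomics": (balanced[sel_feat], features[sel_feat].iloc[va]),
            "combined": (balanced[sel_clin + sel_feat],
                         pd.concat([clin_enc[sel_clin], features[sel_feat]],
                                   axis=1).iloc[va]),
        }
        for kind, (train_tab, val_tab) in tables.items():
            model = GradientBoostingBernoulli(**{**cfg.gbdt,
                                                 "random_state": scheme.seed + k})
            m_star = model.optimal_iterations(train_tab.to_numpy(float), yb)
            model.fit(train_tab.to_numpy(float), yb)
            s_tr = model.decision_function(train_tab.to_numpy(float), n_trees=m_star)
            s_va = model.decision_function(val_tab.to_numpy(float), n_trees=m_star)
            a_tr, lo_tr, hi_tr = delong_ci(s_tr, yb)
            a_va, lo_va, hi_va = delong_ci(s_va, y[va])
            reports[kind].models.append(
                ModelResult(a_tr, (lo_tr, hi_tr), a_va, (lo_va, hi_va), m_star))
            reports[kind].feature_names = list(train_tab.columns)
    return reports, per_split_selected


def report_summary(out_dir: str | Path, top_n: int = 12) -> str:
    """Human-readable summary: per-kind best train/validation AUC with CIs
    and the top variable-importance table of the combined model."""
    out = Path(out_dir)
    report = json.loads((out / "eval_report.json").read_text())
    lines = []
    for kind, rep in report.items():
        models = rep["models"]
        best_tr = max(models, key=lambda m: m["train_auc"])
        best_va = max(models, key=lambda m: m["val_auc"])
        lines.append(
            f"{kind:>9}: best train AUC {best_tr['train_auc']:.3f} "
            f"[{best_tr['train_ci'][0]:.3f}-{best_tr['train_ci'][1]:.3f}], "
            f"best validation AUC {best_va['val_auc']:.3f} "
            f"[{best_va['val_ci'][0]:.3f}-{best_va['val_ci'][1]:.3f}]"
        )
    imp = report.get("combined", {}).get("importance_mean") or {}
    sd = report.get("combined", {}).get("importance_sd") or {}
    ranked = sorted(imp.items(), key=lambda kv: -kv[1])[: min(top_n, len(imp))]
    if ranked:
        lines.append("")
        lines.append(f"Top {len(ranked)} variables (combined model, mean +/- SD importance %):")
        for name, val in ranked:
            lines.append(f"  {name:<50} {val:6.2f} +/- {sd.get(name, 0.0):5.2f}")
    return "\n".join(lines)
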