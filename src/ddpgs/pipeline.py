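"""End-to-end orchestration: simulate -> task -> metrics -> QC -> ancestry
-> PGS -> association, from one config, with plain-file stage outputs and a
JSON run manifest.

Every stage writes TSV/JSON so any stage can be re-run standalone; the
association battery is run once per QC mode (none / lenient / conservative),
mirroring a primary analysis plus the two bounce-criterion sensitivity
analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import assign_ancestry, fit_reference_model, write_eigenvec
from .association import DEFAULT_COVARIATES, run_association_battery
from .cohort import Cohort, CohortConfig, apply_exclusions, generate_cohort, generate_reference_panel
from .genetics import compute_pgs, filter_variants, standardize_scores
from .metrics import metrics_table, write_metrics_tsv
from .qc import filter_cohort, qc_table
from .task import TaskConfig, profiles_from_frame, simulate_profiles, write_profiles_tsv

QC_MODES = ("none", "lenient", "conservative")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    n_reference_per_pop: int = 500
    maf_min: float = 0.05
    hwe_p_min: float = 1.0e-3
    miss_max: float = 0.02
    drop_ambiguous: bool = True
    qc_modes: tuple[str, ...] = QC_MODES
    standardize: str = "both"
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.qc_modes) - set(QC_MODES)
        if bad:
            raise ValueError(f"unknown QC modes: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        task_kwargs = raw.pop("task", {})
        if "delays" in task_kwargs:
            task_kwargs["delays"] = tuple(task_kwargs["delays"])
        task = TaskConfig(**task_kwargs)
        if "qc_modes" in raw:
            raw["qc_modes"] = tuple(raw["qc_modes"])
        cfg = cls(cohort=cohort, task=task, **raw)
        # one seed drives everything; the cohort inherits it unless set
        cfg.cohort.seed = raw.get("cohort_seed", cfg.cohort.seed or cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task"]["delays"] = list(d["task"]["delays"])
        d["qc_modes"] = list(d["qc_modes"])
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``manifest.json`` in ``outdir``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(3)
    cohort_cfg = config.cohort
    if cohort_cfg.seed == 0 and config.seed != 0:
        cohort_cfg.seed = config.seed

    manifest: dict = {
        "tool": "ddpgs",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # 1. cohort ---------------------------------------------------------
    cohort: Cohort = generate_cohort(cohort_cfg)
    cohort.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    cohort.genotypes.to_dosage_tsv(out / "genotypes.tsv")
    cohort.truth.to_json(out / "truth.json")
    manifest["stages"]["cohort"] = {
        "n_subjects": len(cohort.subjects),
        "n_variants": len(cohort.genotypes.variants),
    }

    # 2. reference panel + ancestry ------------------------------------
    panel = generate_reference_panel(
        config.n_reference_per_pop, cohort_cfg.pc_separation,
        seed=np.random.default_rng(streams[0]).integers(2**31),
    )
    write_eigenvec(panel, out / "reference.eigenvec", label_col="population")
    model = fit_reference_model(panel)
    assignments = assign_ancestry(cohort.pcs, model)
    assignments.to_csv(out / "ancestry.tsv", sep="\t")
    manifest["stages"]["ancestry"] = {
        "group_sizes": assignments["label"].value_counts().to_dict()
    }

    # 3. task -----------------------------------------------------------
    subj = cohort.subjects
    taskable = subj[~subj["missing_task"].astype(bool)]
    profiles_df = simulate_profiles(
        k=np.exp(taskable["true_log_k"].to_numpy()),
        nonsystematic=taskable["nonsystematic"].to_numpy(),
        inverse_temp=cohort_cfg.choice_inverse_temp,
        config=config.task,
        seed=np.random.default_rng(streams[1]).integers(2**31),
        subject_ids=taskable["subject_id"].tolist(),
    )
    write_profiles_tsv(profiles_df, out / "profiles.tsv")
    manifest["stages"]["task"] = {"n_with_profiles": taskable.shape[0]}

    # 4. exclusions -----------------------------------------------------
    retained, excl = apply_exclusions(subj, profiles_df["subject_id"].unique())
    manifest["stages"]["exclusions"] = excl.as_dict()

    # 5. metrics + QC ---------------------------------------------------
    keep_ids = set(retained["subject_id"])
    profiles_df = profiles_df[profiles_df["subject_id"].isin(keep_ids)]
    profs = list(profiles_from_frame(profiles_df, config.task.delayed_amount))
    metrics = metrics_table(profs)
    write_metrics_tsv(metrics, out / "metrics.tsv")
    qc = qc_table(profs)
    qc.to_csv(out / "qc.tsv", sep="\t", index=False)
    manifest["stages"]["metrics"] = {"n": len(metrics)}

    # 6. variant QC + PGS ----------------------------------------------
    survivors, tallies = filter_variants(
        cohort.genotypes,
        maf_min=config.maf_min,
        hwe_p_min=config.hwe_p_min,
        miss_max=config.miss_max,
        drop_ambiguous=config.drop_ambiguous,
    )
    gm = cohort.genotypes.subset(survivors)
    manifest["stages"]["variant_qc"] = {"n_retained": len(survivors), "removed": tallies}

    groups = assignments["label"]
    pgs_cols = {}
    score_frame = pd.DataFrame(index=pd.Index(cohort.subjects["subject_id"], name="subject_id"))
    n_matched = {}
    for name, wtab in cohort.truth.weights.items():
        wkeep = wtab[wtab["variant_id"].isin(set(survivors))]
        res = compute_pgs(gm, wkeep)
        z = standardize_scores(res.raw, groups)
        score_frame[f"pgs_{name}"] = z
        pgs_cols[f"pgs_{name}"] = name
        n_matched[name] = res.n_matched
    score_frame.to_csv(out / "pgs.tsv", sep="\t")
    manifest["stages"]["pgs"] = {"n_matched": n_matched}

    # 7. association battery per QC mode --------------------------------
    base = retained.drop(columns=[c for c in retained.columns if c.startswith("pgs_")])
    base = base.merge(metrics[["subject_id", "k", "log_k", "auc", "log_auc"]], on="subject_id")
    base = base.merge(qc[["subject_id", "n_reversals"]], on="subject_id")
    base = base.merge(
        assignments["label"].rename("ancestry"),
        left_on="subject_id", right_index=True,
    )
    base = base.merge(score_frame, left_on="subject_id", right_index=True)

    battery_tables = {}
    for mode in config.qc_modes:
        ids = set(filter_cohort(qc, mode))
        data = base[base["subject_id"].isin(ids)]
        battery = run_association_battery(
            data,
            predictors=list(pgs_cols),
            group_col="ancestry",
            covariates=DEFAULT_COVARIATES,
            standardize=config.standardize,
            alpha=config.fdr_alpha,
        )
        path = out / f"associations_{mode}.tsv"
        battery.table.to_csv(path, sep="\t", index=False)
        battery_tables[mode] = battery
        manifest["stages"][f"associations_{mode}"] = {
            "n_tests": len(battery.table),
            "group_sizes": battery.group_sizes,
            "n_flagged": int((battery.table["p_fdr"] <= config.fdr_alpha).sum()),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
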