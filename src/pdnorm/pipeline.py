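"""End-to-end orchestration: simulate -> qc -> fit -> adapt -> deviations -> zdiff -> behavior -> subtypes.

Each stage reads its upstream artifacts from the run directory, writes
tab-delimited outputs plus a JSON manifest (config hash, input hashes, seed),
and is skipped on re-run when its manifest still matches.  All randomness is
seeded from the run config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas, io
from .adaptation import adapt_cohort, adapted_deviation_matrix, split_controls
from .behavior import change_scores, pca_reduce, spearman_fdr
from .clinical import score_clinical_frame
from .cross_sectional import (
    case_control_count_test,
    duration_correlation,
    extreme_counts,
    overlap_map,
)
from .longitudinal import change_significance_map, compute_zdiff, extreme_zdiff_counts
from .model import NormativeModelResults, fit_cohort_models
from .simulate import ClinicalSpec, ReferenceSpec, generate_clinical, generate_reference
from .subtypes import subtype_contrast

STAGES = ("simulate", "qc", "fit", "adapt", "deviations", "zdiff", "behavior",
          "subtypes")


class StageError(RuntimeError):
    def __init__(self, message, missing_stage=None):
        super().__init__(message)
        self.missing_stage = missing_stage


@dataclass
class RunConfig:
    """Seeds, generator specs and analysis settings for one pipeline run."""

    outdir: str = "pdnorm_run"
    seed: int = 0
    reference: dict = field(default_factory=dict)   # ReferenceSpec overrides
    clinical: dict = field(default_factory=dict)    # ClinicalSpec overrides
    n_rois: int = 12           # fitted ROI subset size (focus structures first)
    warp: str = "sinh-arcsinh"
    euler_cutoff: float = 5.0
    extreme_z: float = 1.96
    split_fraction: float = 0.5
    split_seed: int = 1
    cross_k: int = 3
    long_k: int = 8

    def roi_subset(self) -> list[str]:
        rois = list(atlas.FOCUS_STRUCTURES)
        for c in atlas.THICKNESS_COLUMNS:
            if len(rois) >= self.n_rois:
                break
            rois.append(c)
        return rois[: self.n_rois]

    def reference_spec(self) -> ReferenceSpec:
        kw = dict(self.reference)
        kw.setdefault("seed", self.seed)
        kw.setdefault("rois", tuple(self.roi_subset()))
        if isinstance(kw.get("rois"), list):
            kw["rois"] = tuple(kw["rois"])
        if isinstance(kw.get("age_range"), list):
            kw["age_range"] = tuple(kw["age_range"])
        return ReferenceSpec(**kw)

    def clinical_spec(self) -> ClinicalSpec:
        kw = dict(self.clinical)
        kw.setdefault("seed", self.seed + 1)
        return ClinicalSpec(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Stateful runner bound to a config and its output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # ---- plumbing ------------------------------------------------------------

    def _manifest_path(self, stage: str) -> Path:
        return self.outdir / f"manifest_{stage}.json"

    def _write_manifest(self, stage: str, outputs: list[Path], inputs: list[Path]):
        manifest = {
            "stage": stage,
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
            "outputs": {p.name: _hash_file(p) for p in outputs},
        }
        self._manifest_path(stage).write_text(json.dumps(manifest, indent=1))

    def _up_to_date(self, stage: str, outputs: list[Path]) -> bool:
        mpath = self._manifest_path(stage)
        if not mpath.exists() or not all(p.exists() for p in outputs):
            return False
        try:
            manifest = json.loads(mpath.read_text())
        except json.JSONDecodeError:
            return False
        if manifest.get("config_digest") != self.config.digest():
            return False
        return all(
            manifest["outputs"].get(p.name) == _hash_file(p) for p in outputs
        )

    def _require(self, path: Path, produced_by: str) -> Path:
        if not path.exists():
            raise StageError(
                f"missing upstream artifact {path.name}; run stage "
                f"{produced_by!r} first",
                missing_stage=produced_by,
            )
        return path

    def _read(self, path: Path, produced_by: str) -> pd.DataFrame:
        self._require(path, produced_by)
        try:
            return io.read_cohort(path)
        except Exception as exc:
            raise StageError(
                f"corrupt intermediate file {path.name}: {exc}"
            ) from exc

    # ---- stages --------------------------------------------------------------

    def run_stage(self, stage: str, force: bool = False):
        if stage == "all":
            for s in STAGES:
                self.run_stage(s, force=force)
            return
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        getattr(self, f"_stage_{stage}")(force=force)

    def _stage_simulate(self, force=False):
        out = [self.outdir / "reference.tsv", self.outdir / "clinical.tsv",
               self.outdir / "generator_specs.yaml"]
        if not force and self._up_to_date("simulate", out):
            return
        ref_spec = self.config.reference_spec()
        clin_spec = self.config.clinical_spec()
        io.write_cohort(generate_reference(ref_spec), out[0])
        io.write_cohort(generate_clinical(clin_spec, ref_spec), out[1])
        out[2].write_text(yaml.safe_dump(
            {"reference": ref_spec.to_dict(), "clinical": clin_spec.to_dict()},
            sort_keys=True,
        ))
        self._write_manifest("simulate", out, [])

    def _stage_qc(self, force=False):
        src = self.outdir / "clinical.tsv"
        out = [self.outdir / "clinical_qc.tsv", self.outdir / "qc_report.txt"]
        if not force and self._up_to_date("qc", out):
            return
        table = self._read(src, "simulate")
        retained, rep_euler, rep_visits = io.apply_qc(
            table, cutoff=self.config.euler_cutoff
        )
        io.write_cohort(retained, out[0])
        out[1].write_text(
            "# Euler filter\n" + rep_euler.to_text()
            + "# Both-visits filter\n" + rep_visits.to_text()
        )
        self._write_manifest("qc", out, [src])

    def _models_dir(self) -> Path:
        return self.outdir / "models"

    def _stage_fit(self, force=False):
        src = self.outdir / "reference.tsv"
        rois = self.config.roi_subset()
        mdir = self._models_dir()
        out = [mdir / f"{roi}.json" for roi in rois]
        if not force and self._up_to_date("fit", out):
            return
        reference = self._read(src, "simulate")
        mdir.mkdir(exist_ok=True)
        warp = self.config.warp if self.config.warp != "none" else None
        models = fit_cohort_models(reference, rois, warp=warp,
                                   seed=self.config.seed)
        for roi, res in models.items():
            (mdir / f"{roi}.json").write_text(json.dumps(res.to_dict(), indent=1))
        self._write_manifest("fit", out, [src])

    def _load_models(self) -> dict[str, NormativeModelResults]:
        rois = self.config.roi_subset()
        models = {}
        for roi in rois:
            p = self._require(self._models_dir() / f"{roi}.json", "fit")
            models[roi] = NormativeModelResults.from_dict(json.loads(p.read_text()))
        return models

    def _split(self, retained):
        controls = retained[retained["group"] == "control"]
        return split_controls(controls, fraction=self.config.split_fraction,
                              seed=self.config.split_seed)

    def _stage_adapt(self, force=False):
        src = self.outdir / "clinical_qc.tsv"
        adir = self.outdir / "adapted"
        rois = self.config.roi_subset()
        out = [adir / f"{roi}.json" for roi in rois] + [self.outdir / "split.json"]
        if not force and self._up_to_date("adapt", out):
            return
        retained = self._read(src, "qc")
        adapt_set, test_set = self._split(retained)
        models = self._load_models()
        adapted = adapt_cohort(models, adapt_set)
        adir.mkdir(exist_ok=True)
        for roi, am in adapted.items():
            (adir / f"{roi}.json").write_text(json.dumps(am.to_dict(), indent=1))
        (self.outdir / "split.json").write_text(json.dumps({
            "adapt_subjects": sorted(adapt_set["subject_id"].unique().tolist()),
            "test_subjects": sorted(test_set["subject_id"].unique().tolist()),
            "split_seed": self.config.split_seed,
            "fraction": self.config.split_fraction,
        }, indent=1))
        self._write_manifest("adapt", out, [src])

    def _load_adapted(self):
        from .adaptation import AdaptedModel

        adapted = {}
        for roi in self.config.roi_subset():
            p = self._require(self.outdir / "adapted" / f"{roi}.json", "adapt")
            d = json.loads(p.read_text())
            adapted[roi] = AdaptedModel(
                base=NormativeModelResults.from_dict(d["base"]),
                site=d["site"], offset=d["offset"], scale=d["scale"],
                n_adapt=d["n_adapt"], adapt_subjects=tuple(d["adapt_subjects"]),
            )
        return adapted

    def _stage_deviations(self, force=False):
        src = self.outdir / "clinical_qc.tsv"
        out = [self.outdir / f"zscores_visit{v}.tsv" for v in (1, 2)]
        out += [self.outdir / "extreme_summary.tsv",
                self.outdir / "case_control_tests.tsv"]
        out += [self.outdir / f"overlap_visit{v}_{d}.tsv"
                for v in (1, 2) for d in ("negative", "positive")]
        if not force and self._up_to_date("deviations", out):
            return
        retained = self._read(src, "qc")
        adapted = self._load_adapted()
        adapt_set, test_set = self._split(retained)
        split_ids = set(adapt_set["subject_id"])
        scored = retained[~retained["subject_id"].isin(split_ids)]
        rows = []
        tests = []
        for v in (1, 2):
            tab = scored[scored["visit"] == v]
            Z = adapted_deviation_matrix(adapted, tab)
            Z.to_csv(self.outdir / f"zscores_visit{v}.tsv", sep="\t")
            summ = extreme_counts(Z, threshold=self.config.extreme_z)
            groups = tab.set_index("subject_id")["group"]
            for d in ("negative", "positive"):
                counts = summ.negative if d == "negative" else summ.positive
                pat = counts[groups == "patient"]
                con = counts[groups == "control"]
                res = case_control_count_test(pat, con, tail="greater")
                tests.append({"visit": v, "direction": d, "U": res.statistic,
                              "pvalue": res.pvalue, "method": res.method})
                pd.DataFrame({"roi": Z.columns,
                              "overlap_pct": overlap_map(
                                  Z.loc[groups == "patient"],
                                  threshold=self.config.extreme_z, direction=d
                              ).to_numpy()}).to_csv(
                    self.outdir / f"overlap_visit{v}_{d}.tsv", sep="\t", index=False)
            rows.append(pd.DataFrame({
                "subject_id": counts.index, "visit": v,
                "n_negative": summ.negative.to_numpy(),
                "n_positive": summ.positive.to_numpy(),
                "group": groups.reindex(counts.index).to_numpy(),
            }))
        pd.concat(rows).to_csv(self.outdir / "extreme_summary.tsv", sep="\t",
                               index=False)
        pd.DataFrame(tests).to_csv(self.outdir / "case_control_tests.tsv",
                                   sep="\t", index=False)
        self._write_manifest("deviations", out, [src])

    def _stage_zdiff(self, force=False):
        src = self.outdir / "clinical_qc.tsv"
        out = [self.outdir / "zdiff.tsv", self.outdir / "zdiff_significance.tsv",
               self.outdir / "zdiff_extreme_summary.tsv",
               self.outdir / "zdiff_overlap_negative.tsv"]
        if not force and self._up_to_date("zdiff", out):
            return
        retained = self._read(src, "qc")
        adapted = self._load_adapted()
        adapt_set, _ = self._split(retained)
        patients = retained[retained["group"] == "patient"]
        zres = compute_zdiff(adapted, patients, adapt_set)
        zres.zdiff.to_csv(out[0], sep="\t")
        change_significance_map(zres.zdiff).to_csv(out[1], sep="\t")
        summ = extreme_zdiff_counts(zres.zdiff, threshold=self.config.extreme_z)
        pd.DataFrame({
            "subject_id": zres.zdiff.index,
            "n_negative": summ.negative.to_numpy(),
            "n_positive": summ.positive.to_numpy(),
        }).to_csv(out[2], sep="\t", index=False)
        overlap_map(zres.zdiff, threshold=self.config.extreme_z,
                    direction="negative").rename("overlap_pct").to_csv(
            out[3], sep="\t")
        self._write_manifest("zdiff", out, [src])

    def _clinical_scores(self, table):
        sc = score_clinical_frame(table)
        sc.index = pd.Index(table["subject_id"], name="subject_id")
        return sc

    def _stage_behavior(self, force=False):
        src = self.outdir / "clinical_qc.tsv"
        out = [self.outdir / "behavior_cross_sectional.tsv",
               self.outdir / "behavior_longitudinal.tsv",
               self.outdir / "pca_loadings_cross.tsv",
               self.outdir / "pca_loadings_zdiff.tsv"]
        if not force and self._up_to_date("behavior", out):
            return
        retained = self._read(src, "qc")
        self._require(self.outdir / "zscores_visit1.tsv", "deviations")
        self._require(self.outdir / "zdiff.tsv", "zdiff")
        patients = retained[retained["group"] == "patient"]
        reports = []
        loadings = []
        for v in (1, 2):
            Z = pd.read_csv(self.outdir / f"zscores_visit{v}.tsv", sep="\t",
                            index_col=0)
            Zp = Z.loc[Z.index.isin(set(patients["subject_id"]))]
            k = min(self.config.cross_k, min(Zp.shape) - 1)
            dec = pca_reduce(Zp, k=k)
            clin = self._clinical_scores(patients[patients["visit"] == v])
            clin = clin[["moca_adjusted", "updrs_total"]].reindex(dec.scores.index)
            rep = spearman_fdr(dec.scores, clin)
            rep.insert(0, "visit", v)
            reports.append(rep)
            if v == 1:
                loadings.append(dec.loadings)
        pd.concat(reports).to_csv(out[0], sep="\t", index=False)
        loadings[0].to_csv(out[2], sep="\t")

        zdiff = pd.read_csv(self.outdir / "zdiff.tsv", sep="\t", index_col=0)
        k = min(self.config.long_k, min(zdiff.shape) - 1)
        dec = pca_reduce(zdiff, k=k)
        p1 = self._clinical_scores(patients[patients["visit"] == 1])
        p2 = self._clinical_scores(patients[patients["visit"] == 2])
        ch = change_scores(p1, p2, mode="absolute")
        ch = ch.reindex(dec.scores.index)
        rep = spearman_fdr(dec.scores, ch)
        rep.to_csv(out[1], sep="\t", index=False)
        dec.loadings.to_csv(out[3], sep="\t")
        self._write_manifest("behavior", out, [src])

    def _stage_subtypes(self, force=False):
        src = self.outdir / "clinical_qc.tsv"
        out = [self.outdir / "subtype_contrast.txt",
               self.outdir / "subtype_overlap_maps.tsv"]
        if not force and self._up_to_date("subtypes", out):
            return
        retained = self._read(src, "qc")
        self._require(self.outdir / "zdiff.tsv", "zdiff")
        zdiff = pd.read_csv(self.outdir / "zdiff.tsv", sep="\t", index_col=0)
        labels = (
            retained[retained["group"] == "patient"]
            .drop_duplicates("subject_id")
            .set_index("subject_id")["subtype"]
            .reindex(zdiff.index)
        )
        summ = extreme_zdiff_counts(zdiff, threshold=self.config.extreme_z)
        contrast = subtype_contrast(summ.negative, labels, zdiff=zdiff,
                                    threshold=self.config.extreme_z)
        out[0].write_text(contrast.to_text())
        contrast.overlap_maps.to_csv(out[1], sep="\t")
        self._write_manifest("subtypes", out, [src])


def run_pipeline(config: RunConfig, stage: str = "all", force: bool = False):
    PipelineRun(config).run_stage(stage, force=force)
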