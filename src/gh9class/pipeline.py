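"""End-to-end orchestration: build → score → β → cluster → ANN → classify.

``run_pipeline`` chains every stage on a training set plus a query set,
writing each intermediate table (with provenance headers) into an
artifact directory.  ``run_synthetic_pipeline`` generates a
class-architectured family first and runs the same chain on it, which is
the self-contained smoke and validation path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import ann as ann_mod
from . import betafilter, classify, clustering, io, profiles, synthetic


@dataclass
class PipelineConfig:
    seed: int = 0
    n_train: int = 6  # per class
    n_test: int = 20  # per class
    substitution_rate: float = 0.05
    search: profiles.SearchConfig = field(default_factory=profiles.SearchConfig)
    screen: betafilter.ScreenConfig = field(default_factory=betafilter.ScreenConfig)
    rules_mode: str = "derive-midpoint"  # derive-midpoint | derive-minmax | default
    ann_max_steps: int = 20_000
    ann_scaling: str = "standardize"

    def payload(self) -> dict:
        return {
            "seed": self.seed, "n_train": self.n_train, "n_test": self.n_test,
            "substitution_rate": self.substitution_rate,
            "e_class": self.search.e_class, "e_generic": self.search.e_generic,
            "beta_hi": self.screen.beta_hi, "beta_lo": self.screen.beta_lo,
            "delta_min": self.screen.delta_min, "rules_mode": self.rules_mode,
        }


@dataclass
class PipelineResult:
    registry: profiles.ProfileRegistry
    train_beta: pd.DataFrame
    cluster_model: clustering.ClusterModel
    ann_model: ann_mod.ANNModel
    loocv: ann_mod.LoocvResult
    test_beta: pd.DataFrame
    assignments: pd.DataFrame
    report: pd.DataFrame
    taxonomy: pd.DataFrame
    rules: classify.RuleTable


def _train_betas(registry, score_table, training, screen_cfg):
    triples = {}
    for t in training:
        sel = profiles.select_loocv(t.uid, t.class_label, registry)
        triples[t.uid] = profiles.class_means(
            score_table.loc[t.uid], registry, "loocv", sel)
    return triples, betafilter.beta_table(triples, screen_cfg)


def run_core(training, registry, train_scores, test_seqs, test_scores,
             organisms: Mapping[str, str], cfg: PipelineConfig,
             outdir: Optional[Path] = None) -> PipelineResult:
    """The analysis chain shared by synthetic and user-supplied runs."""
    rng = np.random.SeedSequence(cfg.seed)
    seeds = rng.generate_state(3) % (2 ** 31)

    # training-side statistics (leave-one-out profile selection)
    train_triples, train_beta = _train_betas(registry, train_scores, training,
                                             cfg.screen)
    labels = {t.uid: t.class_label for t in training}
    cluster_cfg = clustering.ClusterConfig(seed=int(seeds[0]))
    cluster_model = clustering.fit_with_exclusion(
        dict(train_beta["beta"]), labels, cluster_cfg)

    # ANN: alpha triples -> class centroid
    kept = [t for t in training if t.uid not in cluster_model.excluded_uids]
    alphas = {t.uid: train_beta.loc[t.uid, ["a12", "a23", "a13"]].to_numpy(float)
              for t in kept}
    tcfg = ann_mod.TrainingConfig(seed=int(seeds[1]), max_steps=cfg.ann_max_steps,
                                  input_scaling=cfg.ann_scaling)
    X = np.array([alphas[t.uid] for t in kept])
    y = np.array([cluster_model.centroid_of(t.class_label) for t in kept])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann_model = ann_mod.train(X, y, tcfg)
        loocv_res = ann_mod.loocv(alphas, labels, cluster_model, tcfg)

    # query-side statistics (generic class profiles)
    test_triples = {}
    for sid in test_scores.index:
        try:
            test_triples[sid] = profiles.class_means(
                test_scores.loc[sid], registry, "generic")
        except profiles.DegenerateScoreError:
            continue
    test_beta = betafilter.beta_table(test_triples, cfg.screen)
    reference = {}
    for sid, triple in test_triples.items():
        res = profiles.max_class(triple)
        if res.label is not None:
            reference[sid] = res.label

    test_alpha = {sid: test_beta.loc[sid, ["a12", "a23", "a13"]].to_numpy(float)
                  for sid in test_beta.index}
    beta_pp = {sid: float(ann_mod.predict(ann_model, test_alpha[sid])[0])
               for sid in test_alpha}

    # rule table: packaged defaults or re-derived from the screened subset
    if cfg.rules_mode == "default":
        rules = classify.RuleTable.default()
    else:
        screened = [sid for sid in test_beta.index
                    if test_beta.loc[sid, "partition"] == "AA" and sid in reference]
        if not screened:
            raise RuntimeError("no sequence passed screening; cannot derive rule bounds")
        mode = "midpoint" if cfg.rules_mode.endswith("midpoint") else "minmax"
        rules = classify.derive_rule_bounds(
            {sid: beta_pp[sid] for sid in screened},
            {sid: reference[sid] for sid in screened}, mode=mode)

    assignments = classify.assign_table(
        beta_pp, {sid: test_beta.loc[sid, "a13"] for sid in beta_pp}, rules,
        dict(test_beta["well_spaced"]))
    deltas = {sid: tuple(test_beta.loc[sid, ["d_ab", "d_bc", "d_ac"]])
              for sid in test_beta.index}
    report = classify.evaluate(dict(assignments["label"]), reference,
                               dict(test_beta["partition"]), deltas)
    passing = {sid: bool(test_beta.loc[sid, "partition"] == "AA")
               for sid in test_beta.index}
    taxonomy = classify.summarize_taxonomy(dict(assignments["label"]),
                                           organisms, passing)

    result = PipelineResult(registry, train_beta, cluster_model, ann_model,
                            loocv_res, test_beta, assignments, report,
                            taxonomy, rules)
    if outdir is not None:
        _write_artifacts(result, cfg, Path(outdir))
    return result


def _write_artifacts(res: PipelineResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = cfg.payload()
    io.save_registry(res.registry, outdir / "registry", seed=cfg.seed)
    io.write_tsv(res.train_beta, outdir / "train_beta.tsv", cfg.seed, payload)
    io.write_tsv(res.test_beta, outdir / "test_beta.tsv", cfg.seed, payload)
    io.write_tsv(res.assignments, outdir / "classes.tsv", cfg.seed, payload)
    io.write_tsv(res.report, outdir / "report.tsv", cfg.seed, payload)
    io.write_tsv(res.taxonomy, outdir / "taxonomy.tsv", cfg.seed, payload)
    io.write_json({"centroids": res.cluster_model.centroids,
                   "assignments": res.cluster_model.assignments,
                   "ss_ratio": res.cluster_model.ss_ratio,
                   "excluded": list(res.cluster_model.excluded_uids)},
                  outdir / "cluster.json", cfg.seed)
    io.write_json({"topology": [ann_mod.N_IN, res.ann_model.w1.shape[0], 1],
                   "w1": res.ann_model.w1, "b1": res.ann_model.b1,
                   "w2": res.ann_model.w2, "b2": res.ann_model.b2,
                   "x_center": res.ann_model.x_center,
                   "x_scale": res.ann_model.x_scale,
                   "converged": res.ann_model.converged,
                   "training_error": res.ann_model.training_error,
                   "loocv_chi2": res.loocv.chi2, "loocv_df": res.loocv.df},
                  outdir / "ann.json", cfg.seed)
    io.write_json(res.rules.to_dict(), outdir / "rules.json", cfg.seed)


def run_synthetic_pipeline(cfg: Optional[PipelineConfig] = None,
                           outdir=None) -> PipelineResult:
    """Generate a family, split train/test, and run the full chain."""
    cfg = cfg or PipelineConfig()
    spec = synthetic.FamilySpec(n_per_class=cfg.n_train + cfg.n_test,
                                substitution_rate=cfg.substitution_rate,
                                seed=cfg.seed)
    records, _truth = synthetic.gen_families(spec)
    by_class = {c: [r for r in records if r.class_label == c]
                for c in profiles.CLASSES}
    training = [r for c in profiles.CLASSES for r in by_class[c][:cfg.n_train]]
    test = [r for c in profiles.CLASSES for r in by_class[c][cfg.n_train:]]

    msa_1d, msa_3d = synthetic.family_alignments(training, spec)
    registry = profiles.build_loocv_registry(training, msa_1d, msa_3d)

    train_seqs = {r.uid: r.residues for r in training}
    test_seqs = {r.uid: r.residues for r in test}
    kept_ids = profiles.screen_homologs(test_seqs, registry, cfg.search)
    test_seqs = {k: v for k, v in test_seqs.items() if k in kept_ids}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_scores = profiles.score_profiles(train_seqs, registry, cfg.search)
        test_scores = profiles.score_profiles(test_seqs, registry, cfg.search)
    organisms = {r.uid: r.organism for r in records}
    return run_core(training, registry, train_scores, test_seqs, test_scores,
                    organisms, cfg, outdir)
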