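"""One-command orchestration: simulate -> pretrain -> train -> finetune -> analyze.

Each stage consumes only files written by earlier stages (never in-memory
state), derives its own seed from the global seed plus the stage name, and
records input/output hashes, metrics and durations in a run manifest, so a
rerun with the same configuration reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import code2vec, ehr_io, patient_embed, pheno_tasks, seq_model, strat_analysis
from .synthetic_ehr import SimConfig, SimTruth, generate_cohort, generate_phecode_map, write_cohort

STAGES = ("simulate", "pretrain_codes", "train_transformer", "finetune",
          "analyze")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    preset: str = "desk"            # "desk" (fast) or "full" (production scale)
    seed: int = 0
    n_patients: int = 500
    sim_overrides: dict = field(default_factory=dict)
    run_finetune: bool = True
    transformer_steps: int | None = None
    sbert_steps: int | None = None
    k_range: tuple[int, int] = (2, 8)
    cluster_pca_dim: int | None = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage seed: global seed folded with the stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, name: str, inputs: list[Path], outputs: list[Path],
               seed: int, duration: float, metrics: dict) -> None:
        self.stages[name] = {
            "inputs": {p.name: _sha(p) for p in inputs if p.exists()},
            "outputs": {p.name: _sha(p) for p in outputs if p.exists()},
            "seed": seed,
            "duration_s": round(duration, 2),
            "metrics": metrics,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages}, indent=1,
            default=str))


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"{path.name} not found; run stage '{producing_stage}' first")
    return path


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute all enabled stages in order; fail fast with stage-named errors."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    desk = config.preset == "desk"

    # -- simulate -----------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "simulate")
    sim_cfg = SimConfig(n_patients=config.n_patients, seed=seed,
                        **config.sim_overrides)
    events, demo, surv, truth = generate_cohort(sim_cfg)
    pmap = generate_phecode_map(sim_cfg)
    paths = write_cohort(out, events, demo, surv, truth, pmap)
    manifest.record("simulate", [], list(paths.values()), seed,
                    time.time() - t0,
                    {"n_patients": config.n_patients, "n_events": len(events),
                     "n_cases": int(truth.table["onset_age_years"].notna().sum())})

    # -- pretrain_codes -----------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "pretrain_codes")
    events = ehr_io.read_events(_require(paths["events"], "simulate"))
    vocab = code2vec.filter_vocabulary(events, min_occurrences=5)
    matrix = code2vec.build_frequency_matrix(events, vocab)
    vae_cfg = (code2vec.desk_vae_config(seed=seed) if desk
               else code2vec.VAEConfig(seed=seed))
    vae, vae_hist = code2vec.train_code_vae(matrix, vae_cfg)
    embeddings = code2vec.encode_codes(vae, matrix, vocab)
    emb_path = out / "code_embeddings.tsv"
    embeddings.write_tsv(emb_path)
    vocab_path = out / "vocabulary.txt"
    vocab_path.write_text("\n".join(vocab.tokens) + "\n")
    manifest.record("pretrain_codes", [paths["events"]],
                    [emb_path, vocab_path], seed, time.time() - t0,
                    {"n_codes": vocab.n_codes,
                     "final_train_loss": vae_hist[-1]["train_loss"]})

    # -- train_transformer --------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "train_transformer")
    emb_frame = pd.read_csv(_require(emb_path, "pretrain_codes"), sep="\t")
    vocab = code2vec.Vocabulary(tokens=tuple(
        _require(vocab_path, "pretrain_codes").read_text().split()))
    code_emb = code2vec.CodeEmbeddingMatrix(
        vocab=vocab,
        means=emb_frame.drop(columns="code").to_numpy(np.float32),
        logvars=np.zeros((vocab.n_codes,
                          emb_frame.shape[1] - 1), np.float32))
    tf_cfg = (seq_model.desk_transformer_config(seed=seed)
              if desk else seq_model.TransformerConfig(seed=seed))
    if config.transformer_steps:
        tf_cfg.steps = config.transformer_steps
    if tf_cfg.d_model != code_emb.dim:
        raise ValueError("transformer d_model != code embedding dim")
    corpus = seq_model.build_year_sentences(events, vocab, tf_cfg.max_len)
    pairs = seq_model.make_nextyear_pairs(corpus)
    model, tf_hist = seq_model.train_transformer(pairs, code_emb, tf_cfg)
    pooled = seq_model.pool_corpus(model, corpus)
    pooled_path = out / "pooled_year_vectors.csv"
    pooled.to_csv(pooled_path, index=False)
    rng = np.random.default_rng(seed)
    masked_acc = seq_model.masked_prediction_accuracy(
        model, corpus, tf_cfg.mask_fraction, rng)
    manifest.record("train_transformer", [paths["events"], emb_path],
                    [pooled_path], seed, time.time() - t0,
                    {"n_sentences": len(corpus), "n_pairs": len(pairs),
                     "masked_prediction_accuracy": round(masked_acc, 4),
                     "val_next_year_accuracy":
                         tf_hist[-1].get("val_next_year_accuracy")})

    # -- finetune -----------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "finetune")
    pooled = pd.read_csv(_require(pooled_path, "train_transformer"))
    year_path = out / "year_embeddings.csv"
    mean_path = out / "mean_vectors.csv"
    metrics: dict = {}
    if config.run_finetune:
        rng = np.random.default_rng(seed)
        pair_set = patient_embed.sample_pairs(pooled, n_pairs=8000, rng=rng)
        sb_cfg = (patient_embed.desk_sbert_config(seed=seed) if desk
                  else patient_embed.SBertConfig(seed=seed))
        if config.sbert_steps:
            sb_cfg.training_steps = config.sbert_steps
        sbert, _ = patient_embed.train_sbert(pair_set, sb_cfg)
        years = patient_embed.embed_cohort(sbert, pooled)
        eval_pairs = patient_embed.sample_pairs(pooled, n_pairs=4000, rng=rng)
        metrics["pair_tasks"] = patient_embed.evaluate_pair_tasks(
            sbert, eval_pairs, rng=np.random.default_rng(seed + 1))
    else:
        # downstream consumes pooled (pre-finetune) vectors unchanged
        years = pooled.rename(columns={
            c: f"s{c[1:]}" for c in pooled.columns if c.startswith("e")})
        metrics["substitution"] = "pooled_pre_finetune_vectors"
    years.to_csv(year_path, index=False)
    means = patient_embed.mean_patient_vector(years)
    means.to_csv(mean_path, index=False)
    manifest.record("finetune", [pooled_path], [year_path, mean_path],
                    seed, time.time() - t0, metrics)

    # -- analyze ------------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "analyze")
    years = pd.read_csv(_require(year_path, "finetune"),
                        dtype={"patient_id": str})
    means = pd.read_csv(_require(mean_path, "finetune"),
                        dtype={"patient_id": str})
    pmap = ehr_io.PhecodeMap.read(_require(paths["phecode_map"], "simulate"))
    occurrences = ehr_io.map_to_phecodes(events, pmap)
    onsets = ehr_io.compute_onset_table(occurrences)
    demo = pd.read_csv(paths["demographics"], dtype={"patient_id": str})
    surv = ehr_io.read_survival(paths["survival"])

    index_phe = sim_cfg.index_phecode
    index_onsets = onsets[onsets["phecode"] == index_phe].rename(
        columns={"onset_age_years": "onset_age_years"})
    idx_onsets = index_onsets[["patient_id", "onset_age_years"]]
    cohort_means = strat_analysis.index_cohort_mean_vectors(
        years, idx_onsets, window="post")

    cluster_model = strat_analysis.fit_gmm_bic(
        cohort_means, k_range=range(config.k_range[0], config.k_range[1] + 1),
        seed=seed, pca_dim=config.cluster_pca_dim)
    assign_path = out / "cluster_assignments.csv"
    cluster_model.assignments.to_csv(assign_path, index=False)

    covar = demo.merge(idx_onsets, on="patient_id").rename(
        columns={"onset_age_years": "age_of_onset"})
    covar = covar[["patient_id", "age_of_onset", "gender", "race",
                   "ethnicity", "site"]]
    enrich = strat_analysis.comorbidity_enrichment(
        cluster_model.assignments, occurrences, covar,
        disease_classes=pmap.phecode_class,
        exclude_phecodes={index_phe})
    enrich_path = out / "enrichment.tsv"
    enrich.to_csv(enrich_path, sep="\t", index=False)

    metrics = {"chosen_k": cluster_model.chosen_k,
               "bic": cluster_model.bic,
               "n_enrichment_tests": len(enrich),
               "n_significant": int(enrich["significant"].sum())
               if len(enrich) else 0}
    try:
        surv_cmp = strat_analysis.km_logrank(cluster_model.assignments, surv)
        metrics["survival_global_logrank_p"] = surv_cmp.global_p
        (out / "survival_summary.json").write_text(json.dumps({
            "global_p": surv_cmp.global_p,
            "global_statistic": surv_cmp.global_statistic,
            "n_per_cluster": surv_cmp.n_per_cluster,
            "pairwise": surv_cmp.pairwise.to_dict("records")}, indent=1))
    except ValueError as exc:
        metrics["survival"] = f"skipped: {exc}"
    emerging = strat_analysis.emerging_phenotypes(
        occurrences, idx_onsets, cluster_model.assignments,
        exclude_phecodes={index_phe})
    emerging.to_csv(out / "emerging_phenotypes.tsv", sep="\t", index=False)

    truth = SimTruth.read(paths["truth"])
    t_idx = truth.table.set_index("patient_id")
    merged = cluster_model.assignments.assign(
        subtype=cluster_model.assignments["patient_id"].map(t_idx["subtype"]))
    from sklearn.metrics import adjusted_rand_score
    metrics["ari_vs_true_subtype"] = float(adjusted_rand_score(
        merged["subtype"], merged["cluster"]))
    manifest.record("analyze",
                    [year_path, mean_path, paths["phecode_map"],
                     paths["survival"]],
                    [assign_path, enrich_path], seed, time.time() - t0,
                    metrics)

    manifest.write(out / "manifest.json")
    return manifest
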