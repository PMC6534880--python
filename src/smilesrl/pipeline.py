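"""End-to-end orchestration: fixtures -> QSAR -> pretrain -> finetune -> RL
-> evaluate, with stage checkpointing and seeded reproducibility.

Seed scheme: every stage uses ``seed + offset`` with a fixed per-stage
offset (fixtures +0, qsar +10, pretrain +20, finetune +30, rl +40,
evaluate +50), so stages are individually reproducible and never share a
random stream.  Realized seeds are recorded in the run manifest.

A stage is skipped when all of its output files already exist; once any
stage actually runs, every downstream stage is re-executed so results stay
consistent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from smilesrl import fixtures as fx
from smilesrl import qsar
from smilesrl.evaluate import batch_report
from smilesrl.generator import GeneratorModel, finetune, pretrain
from smilesrl.reinforce import RLConfig, train_rl
from smilesrl.vocab import build_vocabulary

logger = logging.getLogger(__name__)

STAGE_OFFSETS = {"fixtures": 0, "qsar": 10, "pretrain": 20, "finetune": 30,
                 "rl": 40, "evaluate": 50}


@dataclass
class RunConfig:
    seed: int = 0
    corpus_size: int = 2000
    activity_size: int = 600
    motif_prevalence: float = 0.3
    label_noise: float = 0.05
    qsar_algorithm: str = "RF"
    embed_dim: int = 32
    hidden_dim: int = 64
    n_layers: int = 1
    max_steps: int = 100
    pretrain_epochs: int = 50
    finetune_epochs: int = 10
    batch_size: int = 128
    lr: float = 2e-3
    rl_epsilon: float = 0.1
    rl_beta: float = 0.0
    rl_epochs: int = 30
    rl_batch_size: int = 500
    rl_lr: float = 1e-3
    desired_threshold: float = 0.5
    eval_samples: int = 1000

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_OFFSETS[stage]


@dataclass
class StageResult:
    name: str
    skipped: bool
    outputs: list[str] = field(default_factory=list)


def _outputs_exist(outdir: Path, names: list[str]) -> bool:
    return all((outdir / n).exists() for n in names)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages, checkpointing each; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    force = False
    results: list[StageResult] = []

    def stage(name: str, outputs: list[str], fn) -> StageResult:
        nonlocal force
        if not force and _outputs_exist(outdir, outputs):
            res = StageResult(name, skipped=True, outputs=outputs)
        else:
            logger.info("running stage %s", name)
            fn()
            force = True
            res = StageResult(name, skipped=False, outputs=outputs)
        manifest["stages"][name] = {
            "skipped": res.skipped,
            "seed": config.stage_seed(name),
            "outputs": outputs,
        }
        results.append(res)
        return res

    # -- fixtures ------------------------------------------------------
    corpus_path = outdir / "corpus.smi"
    activity_path = outdir / "activity.csv"

    def do_fixtures():
        ccfg = fx.FixtureConfig(n_molecules=config.corpus_size,
                                seed=config.stage_seed("fixtures"),
                                motif_prevalence=config.motif_prevalence,
                                label_noise=config.label_noise)
        corpus = fx.generate_corpus(ccfg)
        fx.write_corpus(corpus_path, corpus)
        acfg = fx.FixtureConfig(n_molecules=config.activity_size,
                                seed=config.stage_seed("fixtures") + 1,
                                motif_prevalence=config.motif_prevalence,
                                label_noise=config.label_noise)
        fx.write_activity_csv(activity_path, fx.generate_activity_set(acfg))

    stage("fixtures", ["corpus.smi", "activity.csv"], do_fixtures)

    # -- qsar ----------------------------------------------------------
    predictor_path = outdir / "predictor.joblib"
    cv_path = outdir / "qsar_cv.tsv"

    def do_qsar():
        records = fx.read_activity_csv(activity_path)
        ds = qsar.curate_activity_dataset(records)
        cv = qsar.crossvalidate(ds, config.qsar_algorithm, k=5,
                                seed=config.stage_seed("qsar"))
        cv_path.write_text(cv.to_tsv())
        model = qsar.train_predictor(ds, config.qsar_algorithm,
                                     seed=config.stage_seed("qsar"))
        model.save(str(predictor_path))

    stage("qsar", ["predictor.joblib", "qsar_cv.tsv"], do_qsar)

    # -- pretrain ------------------------------------------------------
    pretrained_path = outdir / "pretrained.npz"

    def do_pretrain():
        corpus = fx.read_corpus(corpus_path)
        vocab = build_vocabulary(corpus)
        model, log = pretrain(
            corpus, vocab, epochs=config.pretrain_epochs, lr=config.lr,
            batch_size=config.batch_size, embed_dim=config.embed_dim,
            hidden_dim=config.hidden_dim, n_layers=config.n_layers,
            max_steps=config.max_steps, seed=config.stage_seed("pretrain"),
            valid_sample_size=200)
        model.save(str(pretrained_path))
        (outdir / "pretrain_log.tsv").write_text(log.to_tsv())

    stage("pretrain", ["pretrained.npz", "pretrain_log.tsv"], do_pretrain)

    # -- finetune (on the motif-positive molecules of the activity set) --
    finetuned_path = outdir / "finetuned.npz"

    def do_finetune():
        model = GeneratorModel.load(str(pretrained_path))
        records = fx.read_activity_csv(activity_path)
        target = [r.smiles for r in records
                  if r.pchembl is not None and r.pchembl >= qsar.ACTIVITY_THRESHOLD]
        if not target:
            target = [r.smiles for r in records]
        tuned, log = finetune(model, target, epochs=config.finetune_epochs,
                              lr=config.lr, batch_size=config.batch_size,
                              seed=config.stage_seed("finetune"),
                              valid_sample_size=200)
        tuned.save(str(finetuned_path))
        (outdir / "finetune_log.tsv").write_text(log.to_tsv())

    stage("finetune", ["finetuned.npz", "finetune_log.tsv"], do_finetune)

    # -- rl ------------------------------------------------------------
    rl_path = outdir / "rl_model.npz"

    def do_rl():
        g_theta = GeneratorModel.load(str(pretrained_path))
        g_phi = GeneratorModel.load(str(finetuned_path)).copy(frozen=True)
        predictor = qsar.PredictorModel.load(str(predictor_path))
        rl_cfg = RLConfig(epsilon=config.rl_epsilon, beta=config.rl_beta,
                          epochs=config.rl_epochs,
                          batch_size=config.rl_batch_size,
                          seed=config.stage_seed("rl"), lr=config.rl_lr,
                          desired_threshold=config.desired_threshold)
        trained, log = train_rl(g_theta, g_phi, predictor, rl_cfg)
        trained.save(str(rl_path))
        (outdir / "rl_log.tsv").write_text(log.to_tsv())

    stage("rl", ["rl_model.npz", "rl_log.tsv"], do_rl)

    # -- evaluate ------------------------------------------------------
    def do_evaluate():
        model = GeneratorModel.load(str(rl_path))
        predictor = qsar.PredictorModel.load(str(predictor_path))
        batch = model.sample(config.eval_samples,
                             seed=config.stage_seed("evaluate"))
        fx.write_corpus(outdir / "samples.smi", batch.smiles)
        report = batch_report(batch.smiles, predictor,
                              desired_threshold=config.desired_threshold,
                              with_substructures=True)
        (outdir / "report.tsv").write_text(report.to_tsv())

    stage("evaluate", ["samples.smi", "report.tsv"], do_evaluate)

    (outdir / "config.yaml").write_text(config.to_yaml())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
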