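"""File formats, configuration, and the named end-to-end workflows.

Trial tables are UTF-8 CSV with columns ``participant_id, trial_id,
stimulus_id, label_1..label_3`` (empty cells allowed beyond ``label_1``);
embeddings are GloVe text files (one ``word v1 ... v_d`` per line); arrays
travel as NPZ; images as 8-bit RGB PNG.  Every workflow writes a manifest
recording inputs, seeds, package version and outputs, with a reproducible
hash of its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .semantics import EmbeddingModel, RawResponse

logger = logging.getLogger("semvis")

__all__ = [
    "RunConfig",
    "load_trials",
    "save_trials",
    "load_embedding",
    "save_embedding",
    "load_rdm_csv",
    "save_rdm_csv",
    "save_png",
    "run_workflow",
    "WORKFLOWS",
]

TRIAL_COLUMNS = ["participant_id", "trial_id", "stimulus_id", "label_1", "label_2", "label_3"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "."
    inputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def canonical(self) -> str:
        return json.dumps(
            {"seed": self.seed, "inputs": self.inputs, "options": self.options},
            sort_keys=True,
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# trial tables

def load_trials(path) -> tuple[list[RawResponse], list[tuple[int, str]]]:
    """Read a trial-response CSV; returns (records, rejected (line, reason))."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    extra_labels = [
        c for c in df.columns
        if c.startswith("label_") and c.split("_")[1].isdigit() and int(c.split("_")[1]) > 3
    ]
    records, rejected = [], []
    if df.empty:
        logger.warning("trial file %s is empty", path)
        return records, rejected
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if any(row.get(c, "") for c in extra_labels):
            rejected.append((line, "more than 3 labels"))
            continue
        labels = [row[c] for c in ("label_1", "label_2", "label_3")
                  if c in df.columns and row[c]]
        if not labels:
            rejected.append((line, "no labels"))
            continue
        records.append(
            RawResponse(
                trial_id=row["trial_id"],
                participant_id=row["participant_id"],
                stimulus_id=row["stimulus_id"] or None,
                labels=labels,
            )
        )
    for line, reason in rejected:
        logger.warning("rejected line %d: %s", line, reason)
    return records, rejected


def save_trials(records: list[RawResponse], path) -> None:
    rows = []
    for r in records:
        labels = (r.labels + ["", "", ""])[:3]
        rows.append(
            dict(
                participant_id=r.participant_id,
                trial_id=r.trial_id,
                stimulus_id=r.stimulus_id or "",
                label_1=labels[0],
                label_2=labels[1],
                label_3=labels[2],
            )
        )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# embeddings

def load_embedding(path) -> EmbeddingModel:
    """Read a GloVe-format text embedding; inconsistent rows are rejected."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                if line.strip() == "":
                    continue
                raise ValueError(f"line {lineno}: no vector values")
            word, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            elif len(values) != dim:
                raise ValueError(
                    f"line {lineno}: expected {dim} values, got {len(values)}"
                )
            if word in vectors:
                logger.warning("duplicate word %r at line %d: last occurrence wins",
                               word, lineno)
            vectors[word] = np.array(values, dtype=float)
    if not vectors:
        raise ValueError(f"empty embedding file: {path}")
    return EmbeddingModel(vectors)


def save_embedding(embedding: EmbeddingModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in embedding.vocabulary:
            vals = " ".join(f"{x:.6g}" for x in embedding[w])
            fh.write(f"{w} {vals}\n")


# ---------------------------------------------------------------------------
# RDMs and images

def load_rdm_csv(path):
    from .evaluation import RDM

    df = pd.read_csv(path, index_col=0)
    return RDM(distances=df.to_numpy(float), labels=list(df.columns))


def save_rdm_csv(rdm, path) -> None:
    pd.DataFrame(rdm.distances, index=rdm.labels, columns=rdm.labels).to_csv(path)


def save_png(image: np.ndarray, path) -> None:
    """Write an H x W x 3 float image in [0, 1] as 8-bit RGB PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="RGB").save(path)


# ---------------------------------------------------------------------------
# workflows

def _wf_simulate(config: RunConfig, out: Path) -> list[str]:
    from .simulation import (
        make_standard_feature_model,
        make_standard_world,
        simulate_experiment,
    )

    opts = config.options
    world = make_standard_world(
        m=opts.get("m", 40), d=opts.get("d", 32), v=opts.get("v", 64),
        noise_sd=opts.get("noise_sd", 0.5), seed=config.seed,
    )
    fm = make_standard_feature_model(v=opts.get("v", 64), seed=config.seed)
    trials = simulate_experiment(world, fm, t=opts.get("t", 2000), seed=config.seed + 1)
    save_trials(trials.responses, out / "trials.csv")
    np.savez(out / "features.npz", features=trials.features, mapping=world.mapping)
    save_embedding(world.embedding, out / "embedding.txt")
    fm.save(out / "feature_model.npz")
    return ["trials.csv", "features.npz", "embedding.txt", "feature_model.npz"]


def _wf_fit_map(config: RunConfig, out: Path) -> list[str]:
    from .mapping import fit_pipeline
    from .semantics import clean_responses, trial_semantic_vectors

    trials_path = config.inputs["trials"]
    features_path = config.inputs["features"]
    embedding = load_embedding(config.inputs["embedding"])
    records, _ = load_trials(trials_path)
    with np.load(features_path) as z:
        feats = z["features"]
    cleaned, _log = clean_responses(records, embedding)
    vecs, invalid = trial_semantic_vectors(cleaned, embedding)
    valid_ids = {v.trial_id for v in vecs}
    order = [i for i, r in enumerate(records) if r.trial_id in valid_ids]
    sems = np.stack([v.values for v in vecs])
    matrix = fit_pipeline(feats[order], sems,
                          config.options.get("variance_threshold", 0.9))
    matrix.save(out / "matrix.npz")
    if invalid:
        logger.warning("%d trials had no valid response and were excluded", len(invalid))
    return ["matrix.npz"]


def _wf_synthesize(config: RunConfig, out: Path) -> list[str]:
    from .feature_space import FeatureSpaceModel, sample_target_features
    from .simulation import make_toy_extractor
    from .synthesis import SynthesisConfig, synthesize_stimulus

    opts = config.options
    fm = FeatureSpaceModel.load(config.inputs["feature_model"])
    size = opts.get("image_size", 32)
    extractor = make_toy_extractor(fm.n_features, size, seed=config.seed)
    targets = sample_target_features(fm, opts.get("n", 1), seed=config.seed)
    cfg = SynthesisConfig(
        iterations=opts.get("iterations", 300), image_size=size, seed=config.seed,
    )
    files = []
    for i, target in enumerate(targets):
        res = synthesize_stimulus(target, extractor, cfg)
        name = f"stimulus_{i:03d}.png"
        save_png(res.image, out / name)
        files.append(name)
        with open(out / f"stimulus_{i:03d}.json", "w") as fh:
            json.dump(
                {"r_squared": res.r_squared, "achieved": res.achieved.tolist(),
                 "target": target.tolist()},
                fh,
            )
        files.append(f"stimulus_{i:03d}.json")
    return files


def _wf_reconstruct(config: RunConfig, out: Path) -> list[str]:
    from .mapping import VisualSemanticMatrix, concept_to_features
    from .simulation import make_toy_extractor
    from .synthesis import SynthesisConfig, reconstruct_image

    opts = config.options
    matrix = VisualSemanticMatrix.load(config.inputs["matrix"])
    embedding = load_embedding(config.inputs["embedding"])
    concept = opts["concept"]
    rep = concept_to_features(concept, embedding, matrix)
    size = opts.get("image_size", 32)
    extractor = make_toy_extractor(rep.features.shape[0], size, seed=config.seed)
    cfg = SynthesisConfig(
        objective="caricature", iterations=opts.get("iterations", 300),
        image_size=size, seed=config.seed,
    )
    res = reconstruct_image(rep.features, extractor, cfg)
    save_png(res.image, out / f"{concept}.png")
    with open(out / f"{concept}.json", "w") as fh:
        json.dump({"concept": concept, "features": rep.features.tolist(),
                   "final_objective": float(res.trace[-1])}, fh)
    return [f"{concept}.png", f"{concept}.json"]


def _wf_evaluate(config: RunConfig, out: Path) -> list[str]:
    from .evaluation import rsa_compare

    task = config.options.get("task", "rsa")
    if task != "rsa":
        raise ValueError(f"unsupported evaluate task {task!r} in the CLI; "
                         "use the library API for other analyses")
    rdm_model = load_rdm_csv(config.inputs["rdm_model"])
    rdm_behavior = load_rdm_csv(config.inputs["rdm_behavior"])
    res = rsa_compare(rdm_model, rdm_behavior, seed=config.seed)
    with open(out / "rsa.json", "w") as fh:
        json.dump({"rho": res.rho, "p": res.p, "ci": list(res.ci)}, fh)
    return ["rsa.json"]


WORKFLOWS = {
    "simulate": _wf_simulate,
    "fit-map": _wf_fit_map,
    "synthesize": _wf_synthesize,
    "reconstruct": _wf_reconstruct,
    "evaluate": _wf_evaluate,
}


def run_workflow(name: str, config: RunConfig) -> dict:
    """Execute a named pipeline and write a manifest; returns the manifest."""
    if name not in WORKFLOWS:
        raise ValueError(
            f"unknown workflow {name!r}; valid names: {sorted(WORKFLOWS)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = WORKFLOWS[name](config, out)
    manifest = {
        "workflow": name,
        "version": __version__,
        "seed": config.seed,
        "inputs": config.inputs,
        "options": config.options,
        "config_hash": config.config_hash,
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
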