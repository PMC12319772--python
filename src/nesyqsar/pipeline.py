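"""End-to-end workflow: simulate/load → curate → featurize → train → evaluate.

``run_pipeline`` executes the stages in order into a run directory holding
the config snapshot, the curated table, the feature matrix with its scheme
sidecar, per-epoch history, the metrics report and a content hash of every
written artifact, so a run can be re-executed and compared bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .curation import curate, read_raw_csv, standard_scale
from .featurization import FeatureConfig, featurize
from .metrics import EvalReport
from .models import NetworkSpec, TrainConfig, evaluate, train_dnn, train_ltn, training_sat_agg
from .nn import MLP
from .real_logic import GroundedPredicate, KnowledgeBase
from .synthetic import SimulationSpec, simulate_bioactivity_table

__all__ = ["run_pipeline", "save_model", "load_model"]

logger = logging.getLogger("nesyqsar")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_model(model, path) -> None:
    """Persist a trained network (or grounded predicate) to an .npz archive."""
    net = model.network if isinstance(model, GroundedPredicate) else model
    arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(net.biases)})
    spec = {
        "layer_widths": list(net.layer_widths),
        "activation": net.spec.activation,
        "dropout": net.spec.dropout,
    }
    np.savez(path, spec=json.dumps(spec), **arrays)


def load_model(path) -> MLP:
    data = np.load(path, allow_pickle=False)
    spec = json.loads(str(data["spec"]))
    net = MLP(
        NetworkSpec(tuple(spec["layer_widths"]), spec["activation"], spec["dropout"]), seed=0
    )
    for i in range(len(net.weights)):
        net.weights[i][...] = data[f"w{i}"]
        net.biases[i][...] = data[f"b{i}"]
    return net


def run_pipeline(config: RunConfig, out_dir) -> EvalReport:
    """Execute every stage; artifacts and their hashes land in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    hashes: dict[str, str] = {}

    # -- stage 1: obtain raw records ---------------------------------------
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise FileNotFoundError(f"input stage: raw CSV not found at {path}")
        records = read_raw_csv(path)
        logger.info("stage input: read %d records from %s", len(records), path)
    else:
        sim = SimulationSpec(**{"threshold": config.threshold, **config.simulate})
        table, ledger = simulate_bioactivity_table(sim)
        raw_path = out / "raw.csv"
        table.to_csv(raw_path, index=False)
        (out / "ledger.json").write_text(json.dumps(ledger.to_dict(), indent=2))
        records = read_raw_csv(raw_path)
        hashes["raw.csv"] = _sha256(raw_path)
        logger.info("stage input: simulated %d records", len(records))

    # -- stage 2: curation --------------------------------------------------
    curated, log = curate(
        records,
        threshold=config.threshold,
        ratios=tuple(config.ratios),
        seed=config.seed,
        exclusion_band=config.exclusion_band,
    )
    curated_path = out / "curated.csv"
    curated.to_csv(curated_path, index=False)
    (out / "curation_log.json").write_text(json.dumps(log.to_dict(), indent=2))
    hashes["curated.csv"] = _sha256(curated_path)
    logger.info("stage curate: %d/%d records survived", log.n_output, log.n_input)

    # -- stage 3: featurization ---------------------------------------------
    fconfig = FeatureConfig(
        schemes=tuple(config.schemes),
        morgan_bits=tuple(config.morgan_bits),
        morgan_radius=config.morgan_radius,
    )
    features = featurize(curated["canonical_smiles"].tolist(), fconfig)
    (out / "scheme_dims.json").write_text(json.dumps(features.scheme_dims, indent=2))
    logger.info("stage featurize: %d × %d matrix (%s)",
                features.n_compounds, features.dim, dict(features.scheme_dims))

    # -- stage 4: scaling + training ----------------------------------------
    split = curated["split"].to_numpy()
    labels = curated["label"].map(config.label_map).to_numpy(dtype=np.int64)
    scaled, _scaler = standard_scale(features.values, split)
    train_mask, val_mask, test_mask = (split == s for s in ("train", "val", "test"))

    net = NetworkSpec((None, *config.hidden, len(config.label_map)),
                      config.activation, config.dropout)
    tcfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                       learning_rate=config.learning_rate, seed=config.seed)
    val = (scaled[val_mask], labels[val_mask]) if val_mask.any() else None
    extras: dict[str, float] = {}
    if config.model == "ltn":
        kb = KnowledgeBase.binary_classification(
            p_forall=config.p_forall, p_satagg=config.p_satagg,
            satagg_operator=config.satagg_operator, label_map=config.label_map,
        )
        fitted, history = train_ltn(scaled[train_mask], labels[train_mask], kb, net, tcfg, val=val)
        extras["train_sat_agg"] = training_sat_agg(fitted, kb, scaled[train_mask], labels[train_mask])
    elif config.model == "dnn":
        fitted, history = train_dnn(scaled[train_mask], labels[train_mask], net, tcfg, val=val)
    else:
        raise ValueError(f"unknown model {config.model!r}: expected 'ltn' or 'dnn'")
    pd.DataFrame(history).to_csv(out / "history.csv", index_label="epoch")
    save_model(fitted, out / "model.npz")
    logger.info("stage train: %s final loss %.4f", config.model, history["loss"][-1])

    # -- stage 5: evaluation --------------------------------------------------
    active_idx = config.label_map.get("active", 0)
    report = evaluate(fitted, scaled[test_mask], labels[test_mask],
                      positive_label=active_idx, history=history)
    metrics = report.to_dict()
    metrics.update(extras)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    pd.DataFrame(
        [[report.counts.tp, report.counts.fn], [report.counts.fp, report.counts.tn]],
        index=["true_active", "true_inactive"],
        columns=["pred_active", "pred_inactive"],
    ).to_csv(out / "confusion.csv")
    for name in ("history.csv", "metrics.json", "confusion.csv", "model.npz"):
        hashes[name] = _sha256(out / name)
    (out / "hashes.json").write_text(json.dumps(hashes, indent=2))
    logger.info("stage evaluate: accuracy=%.4f f1=%.4f auc=%.4f mcc=%.4f",
                report.accuracy, report.f1, report.roc_auc, report.mcc)
    return report
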