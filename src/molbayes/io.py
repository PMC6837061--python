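"""Checkpoint persistence.

One ``.npz`` archive per fitted estimator: all parameter matrices (flat
vectors and/or particle stacks), the constructor configuration and a
model-kind tag, with shape metadata checked on load so that an archive
produced under a different architecture fails loudly rather than silently
mis-reshaping. Loading restores bit-identical predictions.
"""

from __future__ import annotations

import json

import numpy as np

from .bayes import DropoutConfig, ParticleEnsemble
from .semisup import SemiSupModel, SemiSupReadoutModel


def save_estimator(est, path) -> None:
    """Persist a fitted GraphConvUncertaintyRegressor to one npz archive."""
    arrays: dict[str, np.ndarray] = {}
    meta = {"kind": est.representation, "inference": est.inference,
            "params": _jsonable(est.get_params())}
    if est.params_ is not None:
        arrays["params"] = est.params_
    if est.ensemble_ is not None:
        arrays["particles"] = est.ensemble_.particles
        meta["provenance"] = est.ensemble_.provenance
    if est.embedding_ is not None:
        arrays["embedding_vec"] = est.embedding_.vec
        meta["embedding"] = {
            "context_dim": est.embedding_.context_dim,
            "n_negatives": est.embedding_.n_negatives,
            "mol_keys": list(est.embedding_.mol_keys),
        }
    np.savez_compressed(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_estimator(path):
    """Rebuild a fitted estimator; verifies parameter shapes against config."""
    from .estimators import GraphConvUncertaintyRegressor

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "meta"}
    params = meta["params"]
    for key in ("head_hidden", "elements"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    est = GraphConvUncertaintyRegressor(**params)
    est.config_ = est._config()

    if "embedding_vec" in arrays:
        emb_meta = meta["embedding"]
        embedding = SemiSupModel(
            config=est.config_,
            context_dim=emb_meta["context_dim"],
            n_negatives=emb_meta["n_negatives"],
            vec=arrays["embedding_vec"],
            mol_keys={k: i for i, k in enumerate(emb_meta["mol_keys"])},
        )
        if embedding.packer.size != arrays["embedding_vec"].shape[0]:
            raise ValueError("embedding checkpoint does not match configuration")
        est.embedding_ = embedding
        est.model_ = SemiSupReadoutModel(
            embedding,
            fingerprint=est.fingerprint,
            head_hidden=tuple(est.head_hidden),
        )
    else:
        from .mpnn import MPNNModel

        est.embedding_ = None
        est.model_ = MPNNModel(est.config_)

    expected = est.model_.packer.size
    est.params_ = None
    est.ensemble_ = None
    if "params" in arrays:
        if arrays["params"].shape[0] != expected:
            raise ValueError(
                f"checkpoint parameter size {arrays['params'].shape[0]} does not "
                f"match configured architecture ({expected})"
            )
        est.params_ = arrays["params"]
    if "particles" in arrays:
        if arrays["particles"].shape[1] != expected:
            raise ValueError("particle shapes do not match configured architecture")
        est.ensemble_ = ParticleEnsemble(
            particles=arrays["particles"],
            provenance=meta.get("provenance", "svgd"),
        )
    if est.inference == "dropout":
        est.dropout_config_ = DropoutConfig(
            p=est.dropout_p, n_samples=est.n_forward_samples, seed=est._seed(37)
        )
    est.n_labelled_ = -1  # unknown after reload
    return est


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
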