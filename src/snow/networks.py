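"""Model networks: encoder, time predictor, and the three ZINB decoders.

The encoder maps a cell's (optionally log1p-transformed) count vector to the
mean of a fixed-variance Gaussian posterior over a 32-dimensional latent cell
state z; during training z = mu(x) + sigma_z * eps with a single global
sigma_z.  A separate network of the same shape predicts the (normalized)
sampling time from the counts.  Three decoders of identical architecture map
the concatenation [z, t] to the ZINB parameters:

* f_rho: softmax head -> count fractions summing to 1 per cell;
* f_theta: softplus head (+ small floor) -> strictly positive inverse
  dispersions;
* f_h: sigmoid head clamped to [0.01, 0.99] -> dropout gates, keeping
  log(h) and log(1-h) finite.

All networks are 3 hidden layers of 256 ReLU units by default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_model import SnowConfigError, TimeMap
from .nn import MLP

__all__ = ["ModelConfig", "SnowModel", "TrainedModel"]

CHECKPOINT_FORMAT_VERSION = 1
THETA_FLOOR = 1e-4


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and numerical settings.

    sigma_z is the fixed posterior standard deviation of the latent state;
    the aggregate posterior is shaped by the sliced-Wasserstein penalties
    rather than a KL term, so sigma_z is a modelling constant, not learned.
    input_transform selects what the encoder and time predictor consume:
    'log1p' (default, stabilizes the scale of raw counts) or 'raw'.
    """

    n_genes: int = 0
    latent_dim: int = 32
    hidden_width: int = 256
    n_hidden_layers: int = 3
    sigma_z: float = 0.7
    h_clamp: tuple = (0.01, 0.99)
    input_transform: str = "log1p"
    time_input_gain: float = 8.0

    def __post_init__(self):
        lo, hi = self.h_clamp
        if not (0.0 < lo < hi < 1.0):
            raise SnowConfigError("h_clamp bounds must satisfy 0 < lo < hi < 1")
        if self.input_transform not in ("log1p", "raw"):
            raise SnowConfigError("input_transform must be 'log1p' or 'raw'")
        if self.sigma_z < 0:
            raise SnowConfigError("sigma_z must be >= 0")


class SnowModel:
    """The five networks plus the forward passes used in training/inference."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        if config.n_genes < 1:
            raise SnowConfigError("ModelConfig.n_genes must be set (>= 1)")
        rng = np.random.default_rng(rng)
        self.config = config
        hidden = [config.hidden_width] * config.n_hidden_layers
        G, D = config.n_genes, config.latent_dim
        self.encoder = MLP(G, hidden, D, rng)
        self.time_net = MLP(G, hidden, 1, rng)
        self.f_rho = MLP(D + 1, hidden, G, rng)
        self.f_theta = MLP(D + 1, hidden, G, rng)
        self.f_h = MLP(D + 1, hidden, G, rng)
        # the scalar time competes with D latent inputs for the first layer's
        # attention; boosting its initial weights speeds up learning of the
        # decoders' time response without changing what they can express
        for net in (self.f_rho, self.f_theta, self.f_h):
            net.layers[0].W.data[-1, :] *= config.time_input_gain

    # -- plumbing ----------------------------------------------------------
    @property
    def nets(self) -> dict[str, MLP]:
        return {
            "encoder": self.encoder,
            "time_net": self.time_net,
            "f_rho": self.f_rho,
            "f_theta": self.f_theta,
            "f_h": self.f_h,
        }

    @property
    def parameters(self) -> list[Tensor]:
        return [p for net in self.nets.values() for p in net.parameters]

    def transform_input(self, counts: np.ndarray) -> np.ndarray:
        x = np.asarray(counts, float)
        return np.log1p(x) if self.config.input_transform == "log1p" else x

    @staticmethod
    def _with_time(z, t_norm):
        """Concatenate latent states with a per-cell scalar time column."""
        if isinstance(z, Tensor):
            n = z.shape[0]
            t_col = t_norm if isinstance(t_norm, Tensor) else Tensor(
                np.broadcast_to(np.reshape(np.asarray(t_norm, float), (-1, 1)), (n, 1)).copy()
            )
            return ad.concat([z, t_col], axis=1)
        z = np.atleast_2d(np.asarray(z, float))
        t_col = np.broadcast_to(np.reshape(np.asarray(t_norm, float), (-1, 1)), (z.shape[0], 1))
        return np.concatenate([z, t_col], axis=1)

    # -- training (graph) passes -------------------------------------------
    def encode_t(self, x: Tensor, eps: np.ndarray | None = None) -> Tensor:
        mu = self.encoder(x)
        if eps is None or self.config.sigma_z == 0.0:
            return mu
        return mu + Tensor(self.config.sigma_z * eps)

    def predict_time_t(self, x: Tensor) -> Tensor:
        return self.time_net(x)

    def decode_rho_t(self, z: Tensor, t_norm) -> Tensor:
        return ad.softmax(self.f_rho(self._with_time(z, t_norm)), axis=1)

    def decode_theta_t(self, z: Tensor, t_norm) -> Tensor:
        return ad.softplus(self.f_theta(self._with_time(z, t_norm))) + THETA_FLOOR

    def decode_h_t(self, z: Tensor, t_norm) -> Tensor:
        lo, hi = self.config.h_clamp
        return ad.sigmoid(self.f_h(self._with_time(z, t_norm))).clip(lo, hi)

    # -- inference (ndarray) passes ----------------------------------------
    def encode(self, counts: np.ndarray) -> np.ndarray:
        """Deterministic latent mean mu(x) for raw count rows."""
        x = self.transform_input(np.atleast_2d(counts))
        self._check_genes(x)
        return self.encoder.forward_np(x)

    def predict_time(self, counts: np.ndarray) -> np.ndarray:
        """Normalized scalar time prediction per cell."""
        x = self.transform_input(np.atleast_2d(counts))
        self._check_genes(x)
        return self.time_net.forward_np(x)[:, 0]

    def decode_rho(self, z: np.ndarray, t_norm) -> np.ndarray:
        logits = self.f_rho.forward_np(self._with_time(z, t_norm))
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def decode_theta(self, z: np.ndarray, t_norm) -> np.ndarray:
        return np.logaddexp(0.0, self.f_theta.forward_np(self._with_time(z, t_norm))) + THETA_FLOOR

    def decode_h(self, z: np.ndarray, t_norm) -> np.ndarray:
        from scipy.special import expit

        lo, hi = self.config.h_clamp
        return np.clip(expit(self.f_h.forward_np(self._with_time(z, t_norm))), lo, hi)

    def _check_genes(self, x: np.ndarray) -> None:
        if x.shape[1] != self.config.n_genes:
            raise ValueError(
                f"input has {x.shape[1]} genes, model expects {self.config.n_genes}"
            )

    def n_parameters(self) -> int:
        return sum(net.n_parameters() for net in self.nets.values())


@dataclass
class TrainedModel:
    """A model plus everything needed to reuse it: the hour<->[0,1] time map,
    the reference library size for virtual cells, gene names, and the training
    loss history."""

    model: SnowModel
    time_map: TimeMap
    l_ref: float
    gene_names: np.ndarray
    loss_history: "pd.DataFrame | None" = None  # noqa: F821
    n_cells_dropped: int = 0

    def save(self, path) -> None:
        import pandas as pd

        arrays = {}
        for net_name, net in self.model.nets.items():
            for i, layer in enumerate(net.layers):
                arrays[f"{net_name}/{i}/W"] = layer.W.data
                arrays[f"{net_name}/{i}/b"] = layer.b.data
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "model_config": {**asdict(self.model.config), "h_clamp": list(self.model.config.h_clamp)},
            "time_map": {"t_min": self.time_map.t_min, "t_max": self.time_map.t_max},
            "l_ref": self.l_ref,
            "n_cells_dropped": self.n_cells_dropped,
        }
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        arrays["__gene_names__"] = np.asarray(self.gene_names, dtype="U")
        if self.loss_history is not None:
            arrays["__loss_columns__"] = np.asarray(self.loss_history.columns, dtype="U")
            arrays["__loss_values__"] = self.loss_history.to_numpy(float)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import pandas as pd

        with np.load(path, allow_pickle=False) as npz:
            arrays = dict(npz)
        meta = json.loads(bytes(arrays.pop("__meta__")).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise SnowConfigError(
                f"checkpoint format {meta['format_version']} not supported"
            )
        cfg_dict = meta["model_config"]
        cfg_dict["h_clamp"] = tuple(cfg_dict["h_clamp"])
        config = ModelConfig(**cfg_dict)
        model = SnowModel(config, rng=0)
        for net_name, net in model.nets.items():
            for i, layer in enumerate(net.layers):
                layer.W.data = arrays[f"{net_name}/{i}/W"]
                layer.b.data = arrays[f"{net_name}/{i}/b"]
        loss_history = None
        if "__loss_values__" in arrays:
            loss_history = pd.DataFrame(
                arrays["__loss_values__"], columns=list(arrays["__loss_columns__"])
            )
        return cls(
            model=model,
            time_map=TimeMap(**meta["time_map"]),
            l_ref=float(meta["l_ref"]),
            gene_names=arrays["__gene_names__"],
            loss_history=loss_history,
            n_cells_dropped=int(meta["n_cells_dropped"]),
        )
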