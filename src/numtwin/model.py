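"""Gain-modulated recurrent convolutional network.

Four recurrent convolutional blocks named after stages of the dorsal visual
stream (V1, V2, V3, IPS) feed a global average pool and a 19-way linear
readout, one unit per possible answer 0..18.  Every nonlinearity is the
gain-scaled rectifier ``y = G * max(0, x)`` preceded by a normalization-only
batch norm, so the input to each nonlinearity has mean 0 and variance 1
during training while the single scalar G controls how strongly neurons
respond — the model's handle on neural excitability.  Within a block the
convolution is applied recurrently with shared weights and a residual skip,
and each recurrent timestep has its own batch-norm statistics; only the last
timestep of each block is exposed for representational analysis.

No pretraining is used anywhere: weights start from seeded He initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, Linear, gain_relu_backward,
                 gain_relu_forward, global_avgpool_backward,
                 global_avgpool_forward, maxpool2x2_backward,
                 maxpool2x2_forward, softmax_cross_entropy)

LAYERS = ("V1", "V2", "V3", "IPS")

#: The study grid of excitability values: G = 1 + 0.25 k, k = 0..16.
GAIN_GRID_FULL = tuple(round(1.0 + 0.25 * k, 2) for k in range(17))

#: Reduced grid for desk-scale sweeps.
GAIN_GRID_DESK = (1.0, 2.0, 3.0, 4.0, 5.0)

PROFILE_WIDTHS = {
    "desk": (16, 24, 32, 48),
    "full": (64, 128, 256, 512),
}

#: Recurrent timesteps per block, matching the recurrent-CNN family the
#: architecture is adapted from.
RECURRENCE_STEPS = (1, 2, 4, 2)

N_CLASSES = 19


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and initialization settings for one network."""

    gain: float = 1.0
    scale_profile: str = "desk"
    channel_widths: tuple[int, ...] | None = None
    recurrence_steps: tuple[int, ...] = RECURRENCE_STEPS
    n_classes: int = N_CLASSES
    rng_seed: int = 0
    #: "avg" pools IPS globally before the readout (the full-scale choice);
    #: "flatten" feeds all IPS units to the readout, which avoids an overly
    #: narrow bottleneck in reduced-width desk models.
    readout_pool: str = "avg"

    def __post_init__(self) -> None:
        if self.readout_pool not in ("avg", "flatten"):
            raise ConfigError("readout_pool must be 'avg' or 'flatten'")
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        if self.scale_profile not in PROFILE_WIDTHS:
            raise ConfigError(f"unknown profile {self.scale_profile!r}")
        if len(self.recurrence_steps) != len(LAYERS):
            raise ConfigError("need one recurrence count per block")

    @property
    def widths(self) -> tuple[int, ...]:
        return self.channel_widths or PROFILE_WIDTHS[self.scale_profile]

    def with_gain(self, gain: float) -> "ModelConfig":
        return replace(self, gain=gain)

    def to_json(self) -> str:
        return json.dumps({
            "gain": self.gain, "scale_profile": self.scale_profile,
            "channel_widths": self.channel_widths,
            "recurrence_steps": list(self.recurrence_steps),
            "n_classes": self.n_classes, "rng_seed": self.rng_seed,
            "readout_pool": self.readout_pool})

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        cw = d["channel_widths"]
        return cls(gain=d["gain"], scale_profile=d["scale_profile"],
                   channel_widths=tuple(cw) if cw else None,
                   recurrence_steps=tuple(d["recurrence_steps"]),
                   n_classes=d["n_classes"], rng_seed=d["rng_seed"],
                   readout_pool=d.get("readout_pool", "avg"))


class RecurrentBlock:
    """Shared-weight recurrent convolution with residual skip.

    First pass: ``u0 = G relu(BN(conv_in(x)))``.  Recurrent passes
    (``steps - 1`` of them): ``u_{t+1} = G relu(BN_t(conv_rec(u_t)) + u_t)``.
    The skip bypasses normalization, so increasing G tilts the update toward
    copying the previous state rather than the newly computed features.
    """

    def __init__(self, cin: int, cout: int, steps: int, gain: float,
                 rng: np.random.Generator, first: bool = False,
                 dtype=np.float32) -> None:
        self.steps = steps
        self.gain = float(gain)
        if first:
            self.conv_in = Conv2d(cin, cout, 5, stride=2, pad=2, rng=rng,
                                  input_grad=False, dtype=dtype)
        else:
            self.conv_in = Conv2d(cin, cout, 3, rng=rng, dtype=dtype)
        self.bn_in = BatchNorm2d(cout, dtype=dtype)
        self.conv_rec = None
        self.bn_rec: list[BatchNorm2d] = []
        if steps > 1:
            self.conv_rec = Conv2d(cout, cout, 3, rng=rng, dtype=dtype)
            self.bn_rec = [BatchNorm2d(cout, dtype=dtype)
                           for _ in range(steps - 1)]

    @property
    def params(self):
        p = list(self.conv_in.params)
        if self.conv_rec is not None:
            p += self.conv_rec.params
        return p

    @property
    def bns(self) -> list[BatchNorm2d]:
        return [self.bn_in] + self.bn_rec

    def forward(self, x: np.ndarray, train: bool):
        z, c_conv = self.conv_in.forward(x)
        h, c_bn = self.bn_in.forward(z, train)
        u, mask = gain_relu_forward(h, self.gain)
        caches = [("in", c_conv, c_bn, mask)]
        for t in range(self.steps - 1):
            z, c_conv = self.conv_rec.forward(u)
            h, c_bn = self.bn_rec[t].forward(z, train)
            u, mask = gain_relu_forward(h + u, self.gain)
            caches.append(("rec", t, c_conv, c_bn, mask))
        return u, caches

    def backward(self, du: np.ndarray, caches) -> np.ndarray | None:
        for entry in reversed(caches[1:]):
            _, t, c_conv, c_bn, mask = entry
            dpre = gain_relu_backward(du, mask, self.gain)
            dz = self.bn_rec[t].backward(dpre, c_bn)
            du = self.conv_rec.backward(dz, c_conv) + dpre
        _, c_conv, c_bn, mask = caches[0]
        dpre = gain_relu_backward(du, mask, self.gain)
        dz = self.bn_in.backward(dpre, c_bn)
        return self.conv_in.backward(dz, c_conv)


class GainNet:
    """The full network: V1 -> V2 -> V3 -> IPS -> pool -> linear readout."""

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.rng_seed)
        widths = config.widths
        self.blocks: list[RecurrentBlock] = []
        cin = 3
        for i, (cout, steps) in enumerate(zip(widths,
                                              config.recurrence_steps)):
            self.blocks.append(RecurrentBlock(cin, cout, steps, config.gain,
                                              rng, first=(i == 0),
                                              dtype=dtype))
            cin = cout
        # spatial extent after the stride-2 V1 conv and the inter-block pools
        h, w = 14, 70
        for _ in range(len(widths) - 1):
            h, w = (h + 1) // 2, (w + 1) // 2
        self._ips_hw = (h, w)
        n_readout = widths[-1] * (h * w if config.readout_pool == "flatten"
                                  else 1)
        self.readout = Linear(n_readout, config.n_classes, rng=rng,
                              dtype=dtype)

    @property
    def params(self):
        p = []
        for b in self.blocks:
            p += b.params
        return p + self.readout.params

    @property
    def gain(self) -> float:
        return self.config.gain

    # -- forward / backward -------------------------------------------------

    def forward(self, images: np.ndarray, train: bool = False,
                need_caches: bool = False, capture: bool = False):
        """Run the network; returns (logits, activations, caches).

        ``activations`` maps layer name to the flattened (batch, units)
        last-timestep activations when ``capture`` is set, else is empty.
        """
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (3, 28, 140):
            raise ValueError(f"expected (n, 3, 28, 140) images, got {x.shape}")
        acts: dict[str, np.ndarray] = {}
        caches = []
        for i, block in enumerate(self.blocks):
            u, bc = block.forward(x, train)
            if capture:
                acts[LAYERS[i]] = u.reshape(u.shape[0], -1).copy()
            if i < len(self.blocks) - 1:
                x, pc = maxpool2x2_forward(u)
            elif self.config.readout_pool == "flatten":
                x, pc = u.reshape(u.shape[0], -1), u.shape
            else:
                x, pc = global_avgpool_forward(u)
            caches.append((bc, pc))
        logits, lc = self.readout.forward(x)
        caches.append(lc)
        return logits, acts, (caches if need_caches else None)

    def backward(self, dlogits: np.ndarray, caches) -> None:
        dx = self.readout.backward(dlogits, caches[-1])
        for i in reversed(range(len(self.blocks))):
            bc, pc = caches[i]
            if i < len(self.blocks) - 1:
                du = maxpool2x2_backward(dx, pc)
            elif self.config.readout_pool == "flatten":
                du = dx.reshape(pc)
            else:
                du = global_avgpool_backward(dx, pc)
            dx = self.blocks[i].backward(du, bc)

    def train_step(self, images: np.ndarray, labels: np.ndarray,
                   optimizer: Adam) -> float:
        logits, _, caches = self.forward(images, train=True, need_caches=True)
        loss, dlogits = softmax_cross_entropy(logits, labels)
        optimizer.zero_grad()
        self.backward(dlogits, caches)
        optimizer.step()
        return loss

    def predict(self, images: np.ndarray) -> np.ndarray:
        logits, _, _ = self.forward(images, train=False)
        return logits.argmax(axis=1)

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"params": [p.value.copy() for p in self.params]}
        bn_state = []
        for b in self.blocks:
            for bn in b.bns:
                bn_state.append((bn.running_mean.copy(),
                                 bn.running_var.copy()))
        state["bn"] = bn_state
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.params, state["params"]):
            p.value[...] = v
        bns = [bn for b in self.blocks for bn in b.bns]
        for bn, (mu, var) in zip(bns, state["bn"]):
            bn.running_mean[...] = mu
            bn.running_var[...] = var


def build_model(config: ModelConfig, dtype=np.float32) -> GainNet:
    """Instantiate a network, enforcing the 19-way readout of the task."""
    if config.n_classes != N_CLASSES:
        raise ConfigError(
            f"the arithmetic task has {N_CLASSES} possible answers; "
            f"got n_classes={config.n_classes}")
    return GainNet(config, dtype=dtype)


def forward_with_activations(model: GainNet, images: np.ndarray):
    """Class scores plus flattened last-timestep activations per layer."""
    logits, acts, _ = model.forward(images, train=False, capture=True)
    return logits, acts


# -- checkpoint persistence --------------------------------------------------

def save_checkpoint(path: str, model: GainNet, optimizer: Adam | None = None,
                    meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = model.config.to_json()
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        state = model.state_dict()
        g = f.create_group("params")
        for i, v in enumerate(state["params"]):
            g.create_dataset(str(i), data=v)
        g = f.create_group("bn")
        for i, (mu, var) in enumerate(state["bn"]):
            g.create_dataset(f"mean{i}", data=mu)
            g.create_dataset(f"var{i}", data=var)
        if optimizer is not None:
            o = f.create_group("adam")
            o.attrs["t"] = optimizer.t
            for i, p in enumerate(optimizer.params):
                o.create_dataset(f"m{i}", data=p.m)
                o.create_dataset(f"v{i}", data=p.v)


def load_checkpoint(path: str,
                    optimizer_params: bool = False) -> tuple[GainNet, dict]:
    with h5py.File(path, "r") as f:
        config = ModelConfig.from_json(f.attrs["config"])
        model = build_model(config)
        n_params = len(model.params)
        state = {
            "params": [f["params"][str(i)][...] for i in range(n_params)],
            "bn": [(f["bn"][f"mean{i}"][...], f["bn"][f"var{i}"][...])
                   for i in range(len(f["bn"]) // 2)],
        }
        model.load_state_dict(state)
        extra: dict = {}
        if "meta" in f.attrs:
            extra["meta"] = json.loads(f.attrs["meta"])
        if optimizer_params and "adam" in f:
            extra["adam"] = {
                "t": int(f["adam"].attrs["t"]),
                "m": [f["adam"][f"m{i}"][...] for i in range(n_params)],
                "v": [f["adam"][f"v{i}"][...] for i in range(n_params)],
            }
    return model, extra
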