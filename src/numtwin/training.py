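"""Gain-sweep training protocol.

Trains one network per excitability value G on identical data streams
(cross-entropy loss, Adam, eta = 0.001, batches of 100), evaluating on the
held-out split every ``eval_every`` optimizer steps — including iteration 0,
before any weight update, where a balanced test set pins accuracy at chance
(1/19).  Each evaluation snapshot stores the 19 x 19 response-count matrix,
the model weights (for exact resumption), and optionally the per-problem mean
activations used by the representational analyses.  ``extended_train``
implements remediation: resuming a snapshot at fixed G and training until a
target accuracy is reached or a censoring cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .model import (GAIN_GRID_DESK, LAYERS, GainNet, ModelConfig, build_model)
from .nn import Adam
from .stimuli import StimulusDataset


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and evaluation schedule for a gain sweep."""

    learning_rate: float = 1e-3
    batch_size: int = 100
    eval_every: int = 100
    max_iterations: int = 500
    gains: tuple[float, ...] = GAIN_GRID_DESK
    rng_seed: int = 0
    #: iterations at which all four layers' mean problem activations are kept
    #: (IPS is kept at every checkpoint); empty -> final iteration only.
    capture_iterations: tuple[int, ...] = ()
    #: balanced cap on test variants per problem used at each evaluation
    #: (None = the whole held-out split).
    eval_variants_per_problem: int | None = 5

    def __post_init__(self) -> None:
        if not self.gains:
            raise ValueError("gain list must be non-empty")
        if self.eval_every < 1 or self.batch_size < 1:
            raise ValueError("eval_every and batch_size must be >= 1")

    @property
    def full_capture_iterations(self) -> tuple[int, ...]:
        return self.capture_iterations or (self.max_iterations,)


@dataclass
class SweepCheckpoint:
    """Evaluation snapshot for one (gain, iteration)."""

    gain: float
    iteration: int
    test_accuracy: float
    response_matrix: np.ndarray             # (19, 19): [true result, response]
    mean_activations: dict[str, np.ndarray] = field(default_factory=dict)
    model_state: dict | None = None
    adam_state: dict | None = None


@dataclass
class SweepResult:
    checkpoints: list[SweepCheckpoint]
    train_config: TrainConfig
    model_config: ModelConfig

    @property
    def gains(self) -> tuple[float, ...]:
        return self.train_config.gains

    @property
    def iterations(self) -> list[int]:
        return sorted({c.iteration for c in self.checkpoints})

    def checkpoint(self, gain: float, iteration: int) -> SweepCheckpoint:
        for c in self.checkpoints:
            if c.gain == gain and c.iteration == iteration:
                return c
        raise KeyError(f"no checkpoint for gain={gain}, iteration={iteration}")

    def trace(self, gain: float) -> list[tuple[int, float]]:
        return sorted((c.iteration, c.test_accuracy)
                      for c in self.checkpoints if c.gain == gain)

    def accuracy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gain": c.gain, "iteration": c.iteration,
              "accuracy": c.test_accuracy} for c in self.checkpoints]
        ).sort_values(["gain", "iteration"]).reset_index(drop=True)


def balanced_test_indices(dataset: StimulusDataset,
                          max_per_problem: int | None) -> np.ndarray:
    """The held-out split, optionally capped to the first ``max_per_problem``
    test variants of every problem (keeps per-result balance exact)."""
    test_idx = dataset.test_indices
    if max_per_problem is None:
        return test_idx
    keep = []
    for pid in range(len(dataset.problems)):
        rows = test_idx[dataset.problem_ids[test_idx] == pid]
        keep.append(rows[:max_per_problem])
    return np.concatenate(keep)


def evaluate(model: GainNet, dataset: StimulusDataset,
             capture_layers: tuple[str, ...] = (),
             batch_size: int = 200,
             max_per_problem: int | None = None) -> SweepCheckpoint:
    """Accuracy, response-count matrix and optional per-problem mean
    activations on the (balanced) held-out test split."""
    n_classes = model.config.n_classes
    n_problems = len(dataset.problems)
    resp = np.zeros((n_classes, n_classes), dtype=np.int64)
    sums = {layer: None for layer in capture_layers}
    counts = np.zeros(n_problems, dtype=np.int64)
    test_idx = balanced_test_indices(dataset, max_per_problem)
    for start in range(0, len(test_idx), batch_size):
        idx = test_idx[start:start + batch_size]
        images = dataset.images_float(idx)
        logits, acts, _ = model.forward(images, train=False,
                                        capture=bool(capture_layers))
        preds = logits.argmax(axis=1)
        np.add.at(resp, (dataset.labels[idx], preds), 1)
        pids = dataset.problem_ids[idx]
        np.add.at(counts, pids, 1)
        for layer in capture_layers:
            a = acts[layer]
            if sums[layer] is None:
                sums[layer] = np.zeros((n_problems, a.shape[1]),
                                       dtype=np.float64)
            np.add.at(sums[layer], pids, a)
    accuracy = float(np.trace(resp) / resp.sum())
    means = {layer: (s / counts[:, None]).astype(np.float32)
             for layer, s in sums.items()}
    return SweepCheckpoint(gain=model.gain, iteration=-1,
                           test_accuracy=accuracy, response_matrix=resp,
                           mean_activations=means)


def batch_stream(n_train: int, config: TrainConfig,
                 n_iterations: int | None = None) -> np.ndarray:
    """Pre-drawn batch indices, shared across gains so every model sees the
    same example stream (uniform with replacement; the structural balance of
    the dataset makes batches label-balanced in expectation)."""
    rng = np.random.default_rng(config.rng_seed)
    n_iter = n_iterations if n_iterations is not None else config.max_iterations
    return rng.integers(0, n_train, size=(n_iter, config.batch_size))


def _capture_layers_at(iteration: int, config: TrainConfig):
    if iteration in config.full_capture_iterations:
        return LAYERS
    return ("IPS",)


def train_one_gain(dataset: StimulusDataset, config: TrainConfig,
                   model_config: ModelConfig, gain: float,
                   batches: np.ndarray) -> list[SweepCheckpoint]:
    model = build_model(model_config.with_gain(gain))
    opt = Adam(model.params, lr=config.learning_rate)
    train_idx = dataset.train_indices
    checkpoints = []

    def snapshot(iteration: int) -> None:
        cp = evaluate(model, dataset,
                      capture_layers=_capture_layers_at(iteration, config),
                      max_per_problem=config.eval_variants_per_problem)
        cp.iteration = iteration
        cp.model_state = model.state_dict()
        cp.adam_state = opt.state_dict()
        checkpoints.append(cp)

    snapshot(0)
    for it in range(1, config.max_iterations + 1):
        idx = train_idx[batches[it - 1]]
        model.train_step(dataset.images_float(idx), dataset.labels[idx], opt)
        if it % config.eval_every == 0:
            snapshot(it)
    return checkpoints


def train_sweep(dataset: StimulusDataset, config: TrainConfig,
                model_config: ModelConfig,
                progress: bool = False) -> SweepResult:
    """Train one model per gain on the shared batch stream."""
    batches = batch_stream(len(dataset.train_indices), config)
    checkpoints: list[SweepCheckpoint] = []
    for gain in config.gains:
        if progress:
            print(f"[sweep] training gain G={gain}")
        checkpoints.extend(
            train_one_gain(dataset, config, model_config, gain, batches))
    return SweepResult(checkpoints=checkpoints, train_config=config,
                       model_config=model_config)


def iterations_to_threshold(trace: list[tuple[int, float]],
                            threshold: float = 0.95) -> int | None:
    """First checkpoint iteration whose accuracy meets the threshold.

    Returns None when the threshold is never reached within the trace.
    """
    if not trace:
        raise ValueError("trace must be non-empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    for iteration, accuracy in sorted(trace):
        if accuracy >= threshold:
            return iteration
    return None


@dataclass
class ExtendedTrainResult:
    gain: float
    start_iteration: int
    additional_iterations: int
    percent_of_initial: float
    censored: bool
    final_accuracy: float
    trace: list[tuple[int, float]]          # (additional iteration, accuracy)
    checkpoints: list[SweepCheckpoint]


def extended_train(checkpoint: SweepCheckpoint, dataset: StimulusDataset,
                   target_accuracy: float, config: TrainConfig,
                   model_config: ModelConfig,
                   cap_factor: float = 5.0) -> ExtendedTrainResult:
    """Resume a snapshot at unchanged gain until the target accuracy.

    The data stream continues exactly where the sweep left off.  If the
    target is not reached within ``cap_factor * start_iteration`` additional
    steps, the run is reported as censored rather than raising.
    """
    if checkpoint.model_state is None:
        raise ValueError("checkpoint does not carry model state to resume")
    t0 = checkpoint.iteration
    cap = max(int(np.ceil(cap_factor * max(t0, 1))), config.eval_every)
    model = build_model(model_config.with_gain(checkpoint.gain))
    model.load_state_dict(checkpoint.model_state)
    opt = Adam(model.params, lr=config.learning_rate)
    if checkpoint.adam_state is not None:
        opt.load_state_dict(checkpoint.adam_state)

    def accuracy_now() -> float:
        return evaluate(model, dataset,
                        max_per_problem=config.eval_variants_per_problem
                        ).test_accuracy

    trace = [(0, accuracy_now())]
    checkpoints: list[SweepCheckpoint] = []
    if trace[0][1] >= target_accuracy:
        return ExtendedTrainResult(
            gain=checkpoint.gain, start_iteration=t0, additional_iterations=0,
            percent_of_initial=0.0, censored=False,
            final_accuracy=trace[0][1], trace=trace, checkpoints=checkpoints)

    stream = batch_stream(len(dataset.train_indices), config,
                          n_iterations=t0 + cap)
    train_idx = dataset.train_indices
    extra = 0
    reached = None
    while extra < cap:
        extra += 1
        idx = train_idx[stream[t0 + extra - 1]]
        model.train_step(dataset.images_float(idx), dataset.labels[idx], opt)
        if extra % config.eval_every == 0 or extra == cap:
            cp = evaluate(model, dataset,
                          max_per_problem=config.eval_variants_per_problem)
            cp.iteration = t0 + extra
            cp.model_state = model.state_dict()
            checkpoints.append(cp)
            trace.append((extra, cp.test_accuracy))
            if cp.test_accuracy >= target_accuracy:
                reached = extra
                break
    censored = reached is None
    additional = cap if censored else reached
    return ExtendedTrainResult(
        gain=checkpoint.gain, start_iteration=t0,
        additional_iterations=additional,
        percent_of_initial=100.0 * additional / max(t0, 1),
        censored=censored, final_accuracy=trace[-1][1], trace=trace,
        checkpoints=checkpoints)


# -- persistence -------------------------------------------------------------

def save_sweep(path: str, sweep: SweepResult) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model_config"] = sweep.model_config.to_json()
        tc = sweep.train_config
        f.attrs["train_config"] = pd.Series({
            "learning_rate": tc.learning_rate, "batch_size": tc.batch_size,
            "eval_every": tc.eval_every, "max_iterations": tc.max_iterations,
            "rng_seed": tc.rng_seed}).to_json()
        f.attrs["gains"] = list(tc.gains)
        f.attrs["capture_iterations"] = list(tc.full_capture_iterations)
        for i, c in enumerate(sweep.checkpoints):
            g = f.create_group(f"checkpoint_{i}")
            g.attrs["gain"] = c.gain
            g.attrs["iteration"] = c.iteration
            g.attrs["test_accuracy"] = c.test_accuracy
            g.create_dataset("response_matrix", data=c.response_matrix)
            for layer, acts in c.mean_activations.items():
                g.create_dataset(f"acts_{layer}", data=acts,
                                 compression="gzip")
            if c.model_state is not None:
                s = g.create_group("state")
                for j, v in enumerate(c.model_state["params"]):
                    s.create_dataset(f"p{j}", data=v)
                for j, (mu, var) in enumerate(c.model_state["bn"]):
                    s.create_dataset(f"bn_mean{j}", data=mu)
                    s.create_dataset(f"bn_var{j}", data=var)


def load_sweep(path: str, model_config: ModelConfig | None = None,
               train_config: TrainConfig | None = None) -> SweepResult:
    import json as _json
    with h5py.File(path, "r") as f:
        mc = model_config or ModelConfig.from_json(f.attrs["model_config"])
        tcd = _json.loads(f.attrs["train_config"])
        tc = train_config or TrainConfig(
            learning_rate=tcd["learning_rate"],
            batch_size=int(tcd["batch_size"]),
            eval_every=int(tcd["eval_every"]),
            max_iterations=int(tcd["max_iterations"]),
            gains=tuple(float(g) for g in f.attrs["gains"]),
            rng_seed=int(tcd["rng_seed"]),
            capture_iterations=tuple(
                int(i) for i in f.attrs["capture_iterations"]))
        checkpoints = []
        i = 0
        while f"checkpoint_{i}" in f:
            g = f[f"checkpoint_{i}"]
            acts = {k[len("acts_"):]: g[k][...] for k in g
                    if k.startswith("acts_")}
            state = None
            if "state" in g:
                s = g["state"]
                n_p = len([k for k in s if k.startswith("p")])
                n_bn = len([k for k in s if k.startswith("bn_mean")])
                state = {"params": [s[f"p{j}"][...] for j in range(n_p)],
                         "bn": [(s[f"bn_mean{j}"][...], s[f"bn_var{j}"][...])
                                for j in range(n_bn)]}
            checkpoints.append(SweepCheckpoint(
                gain=float(g.attrs["gain"]),
                iteration=int(g.attrs["iteration"]),
                test_accuracy=float(g.attrs["test_accuracy"]),
                response_matrix=g["response_matrix"][...],
                mean_activations=acts, model_state=state))
            i += 1
    return SweepResult(checkpoints=checkpoints, train_config=tc,
                       model_config=mc)
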