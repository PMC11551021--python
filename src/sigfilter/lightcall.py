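"""LightCall: a lightweight convolutional CTC basecaller.

The network is a plain sequential stack — an input stem convolution that
downsamples the signal in time, a number of blocks of [grouped 1-D conv →
batch-norm → ReLU → pointwise 1-D conv → batch-norm → ReLU], and a
pointwise projection to 5 classes (4 bases + CTC blank) with log-softmax
output per position. There are deliberately no skip connections: the model
trades accuracy for throughput, producing *noisy* reads that are good
enough for reference classification but not for downstream analysis.

Long signals are basecalled by splitting them into fixed-length chunks,
greedy-decoding each chunk and concatenating the decoded fragments in
order. Training minimises the CTC loss with Adam and decoupled weight
decay; ground-truth bases are apportioned to chunks using the per-base
sample spans recorded by the simulator.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import ctc, nn
from .siggen import SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "TrainConfig", "ChunkSet", "NoisyRead", "LightCallModel",
    "normalize_signal", "chunk_signal", "build_model", "count_parameters",
    "ctc_greedy_decode", "basecall_read", "train_model",
    "save_checkpoint", "load_checkpoint", "load_preset", "PRESET_NAMES",
]

ctc_greedy_decode = ctc.ctc_greedy_decode

#: frozen configuration family (width/blocks chosen once to land on the
#: published parameter counts; see docs/methods.md)
PRESET_NAMES = ("lcmain_x2", "lcmain", "lcmain_div2", "lcmain_div4", "lcmain_div8")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of a LightCall model.

    ``groups=None`` means depthwise (groups == width). The alphabet is
    fixed to A, C, G, T plus the CTC blank, i.e. 5 output classes.
    """

    n_blocks: int
    width: int
    kernel: int = 9
    groups: int | None = None
    stem_kernel: int = 33
    stem_stride: int = 3
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.stem_stride < 1:
            raise ValueError("stem_stride must be >= 1")
        g = self.effective_groups
        if self.width % g:
            raise ValueError(f"width={self.width} not divisible by groups={g}")

    @property
    def effective_groups(self) -> int:
        return self.width if self.groups is None else self.groups

    @property
    def n_classes(self) -> int:
        return ctc.N_CLASSES


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and training-loop settings.

    The Adam hyperparameters default to learning rate 2e-3,
    (beta1, beta2) = (0.9, 0.999), decoupled weight decay 0.01 and
    epsilon 1e-8.
    """

    learning_rate: float = 2e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    epsilon: float = 1e-8
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    chunk_len: int = 1000
    steps_per_epoch: int | None = None
    val_fraction: float = 0.1
    lr_final_factor: float = 0.1
    grad_clip: float = 5.0
    warmup_steps: int = 0


@dataclass
class ChunkSet:
    """Fixed-length windows of one signal plus per-chunk valid lengths."""

    chunks: np.ndarray  # (n_chunks, chunk_len)
    valid_lengths: np.ndarray
    chunk_len: int

    def reassemble(self) -> np.ndarray:
        return np.concatenate(
            [c[:v] for c, v in zip(self.chunks, self.valid_lengths)]
        ) if len(self.chunks) else np.empty(0)


@dataclass
class NoisyRead:
    """A basecalled (noisy) read: concatenation of per-chunk decodes."""

    read_id: str
    sequence: str
    chunk_sequences: list[str] = field(default_factory=list)


def normalize_signal(samples: np.ndarray) -> np.ndarray:
    """Median/MAD normalization with clipping to [-5, 5].

    Output is ``(x - median) / (1.4826 * MAD)``. If the MAD is degenerate
    (< 1e-9) the standard deviation is used instead; if that too is
    degenerate the output is all zeros.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale < 1e-9:
        scale = x.std()
        if scale < 1e-9:
            return np.zeros_like(x)
    return np.clip((x - med) / scale, -5.0, 5.0)


def chunk_signal(samples: np.ndarray, chunk_len: int) -> ChunkSet:
    """Split a signal into non-overlapping chunks, zero-padding the last."""
    if chunk_len < 1:
        raise ValueError("chunk_len must be >= 1")
    x = np.asarray(samples, dtype=np.float32)
    t = x.size
    n_chunks = max(1, -(-t // chunk_len))
    padded = np.zeros(n_chunks * chunk_len, dtype=np.float32)
    padded[:t] = x
    chunks = padded.reshape(n_chunks, chunk_len)
    valid = np.full(n_chunks, chunk_len, dtype=np.int64)
    valid[-1] = t - (n_chunks - 1) * chunk_len
    return ChunkSet(chunks=chunks, valid_lengths=valid, chunk_len=chunk_len)


class LightCallModel:
    """A built LightCall network: sequential layers plus its config."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        w, g = config.width, config.effective_groups
        layers: list[nn.Layer] = [
            nn.Conv1d(1, w, config.stem_kernel, stride=config.stem_stride,
                      bias=False, name="stem.conv", rng=rng),
            nn.BatchNorm1d(w, name="stem.bn"),
            nn.ReLU(),
        ]
        for i in range(config.n_blocks):
            layers += [
                nn.Conv1d(w, w, config.kernel, groups=g, bias=False,
                          name=f"block{i}.grouped", rng=rng),
                nn.BatchNorm1d(w, name=f"block{i}.bn1"),
                nn.ReLU(),
                nn.Conv1d(w, w, 1, bias=False, name=f"block{i}.pointwise",
                          rng=rng),
                nn.BatchNorm1d(w, name=f"block{i}.bn2"),
                nn.ReLU(),
            ]
        layers += [
            nn.Conv1d(w, config.n_classes, 1, bias=True, name="head", rng=rng),
            nn.LogSoftmax(),
        ]
        self.config = config
        self.net = nn.Sequential(layers)

    # -- structure ---------------------------------------------------------
    @property
    def layers(self) -> list[nn.Layer]:
        return self.net.layers

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def output_length(self, t: int) -> int:
        return -(-t // self.config.stem_stride)

    # -- computation -------------------------------------------------------
    def forward(self, chunks: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, T) chunks -> (B, out_positions, 5) log-probabilities."""
        x = np.asarray(chunks, dtype=np.float32)[:, None, :]
        y = self.net.forward(x, training=training)
        return np.transpose(y, (0, 2, 1))

    def backward(self, grad_out: np.ndarray) -> None:
        self.net.backward(np.transpose(grad_out, (0, 2, 1)).astype(np.float32))

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm1d):
                state[layer.gamma.name.rsplit(".", 1)[0] + ".running_mean"] = layer.running_mean
                state[layer.gamma.name.rsplit(".", 1)[0] + ".running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for layer in self.layers:
            if isinstance(layer, nn.BatchNorm1d):
                prefix = layer.gamma.name.rsplit(".", 1)[0]
                layer.running_mean = np.asarray(state[prefix + ".running_mean"],
                                                dtype=np.float32)
                layer.running_var = np.asarray(state[prefix + ".running_var"],
                                               dtype=np.float32)


def build_model(config: ModelConfig, seed: int = 0) -> LightCallModel:
    """Instantiate a LightCall network with He-initialised weights."""
    return LightCallModel(config, rng=np.random.default_rng(seed))


def count_parameters(model: LightCallModel) -> int:
    """Total trainable scalars: conv weights/biases, BN scale/shift, head."""
    return int(sum(p.size for p in model.params()))


def load_preset(name: str) -> ModelConfig:
    """Load one of the frozen configurations shipped with the package."""
    import yaml

    path = Path(__file__).parent / "configs" / f"{name.lower()}.yaml"
    if not path.exists():
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    raw = yaml.safe_load(path.read_text())
    return ModelConfig(**raw)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def basecall_chunks(model: LightCallModel, chunkset: ChunkSet,
                    batch_size: int = 64) -> list[str]:
    """Greedy-decode every chunk, masking positions that come from padding."""
    seqs: list[str] = []
    chunks, valid = chunkset.chunks, chunkset.valid_lengths
    for i in range(0, len(chunks), batch_size):
        lp = model.forward(chunks[i:i + batch_size], training=False)
        for j in range(lp.shape[0]):
            n_valid = model.output_length(int(valid[i + j]))
            seqs.append(ctc.ctc_greedy_decode(lp[j], n_valid))
    return seqs


def basecall_read(model: LightCallModel, record: SignalRecord,
                  chunk_len: int = 4000) -> NoisyRead:
    """Normalize, chunk, decode and merge one read's signal."""
    if record.samples.size == 0:
        raise ValueError("cannot basecall an empty signal")
    normed = normalize_signal(record.samples)
    chunkset = chunk_signal(normed, chunk_len)
    seqs = basecall_chunks(model, chunkset)
    return NoisyRead(read_id=record.read_id, sequence="".join(seqs),
                     chunk_sequences=seqs)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _chunk_labels(record: SignalRecord, chunk_len: int, k: int | None = None
                  ) -> list[np.ndarray]:
    """Assign truth bases to chunks by the sample span of their k-mer.

    Base ``i`` is anchored at the first sample of k-mer position
    ``min(i, n_kmers - 1)`` (the trailing k-1 bases share the last k-mer's
    span), so assignment is exact given the simulator's recorded dwells.
    """
    if record.truth_seq is None or record.dwells is None:
        raise ValueError(f"read {record.read_id!r} lacks truth_seq/dwells")
    classes = ctc.labels_to_classes(record.truth_seq)
    starts = np.concatenate([[0], np.cumsum(record.dwells)[:-1]])
    n_kmers = len(starts)
    anchor = starts[np.minimum(np.arange(len(classes)), n_kmers - 1)]
    chunk_of = anchor // chunk_len
    n_chunks = max(1, -(-record.samples.size // chunk_len))
    return [classes[chunk_of == c] for c in range(n_chunks)]


def make_training_chunks(records: Iterable[SignalRecord], chunk_len: int
                         ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Flatten a set of reads into (chunks, valid_lengths, labels)."""
    all_chunks, all_valid, all_labels = [], [], []
    for rec in records:
        normed = normalize_signal(rec.samples)
        cs = chunk_signal(normed, chunk_len)
        labels = _chunk_labels(rec, chunk_len)
        for i in range(len(cs.chunks)):
            if labels[i].size == 0:
                continue
            all_chunks.append(cs.chunks[i])
            all_valid.append(cs.valid_lengths[i])
            all_labels.append(labels[i])
    if not all_chunks:
        raise ValueError("no non-empty training chunks")
    return np.stack(all_chunks), np.asarray(all_valid), all_labels


def _median_identity(model: LightCallModel, records: Sequence[SignalRecord],
                     chunk_len: int) -> float:
    from .metrics import read_identity

    ids = []
    for rec in records:
        called = basecall_read(model, rec, chunk_len=chunk_len)
        ids.append(read_identity(called.sequence, rec.truth_seq or ""))
    return float(np.median(ids)) if ids else 0.0


def train_model(
    config: ModelConfig,
    train_cfg: TrainConfig,
    records: Sequence[SignalRecord],
) -> tuple[LightCallModel, list[dict]]:
    """Train a LightCall model by CTC on truth-labelled signal records.

    Reads are split into train/validation by ``val_fraction``; the model
    snapshot with the best validation median identity is returned together
    with a per-epoch log of mean loss and validation identity. Chunks whose
    label cannot fit into the available output frames are dropped with a
    warning. Fully seeded: identical configs and data give identical runs.
    """
    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(config, seed=train_cfg.seed)
    records = list(records)
    n_val = max(1, int(round(len(records) * train_cfg.val_fraction))) \
        if train_cfg.val_fraction > 0 and len(records) > 1 else 0
    perm = rng.permutation(len(records))
    val_records = [records[i] for i in perm[:n_val]]
    train_records = [records[i] for i in perm[n_val:]]

    chunks, valid, labels = make_training_chunks(train_records, train_cfg.chunk_len)
    out_lens = np.array([model.output_length(int(v)) for v in valid])
    feasible = np.array(
        [ctc.min_path_frames(lab) <= ol for lab, ol in zip(labels, out_lens)]
    )
    n_drop = int((~feasible).sum())
    if n_drop:
        logger.warning(
            "dropping %d/%d chunks whose label does not fit the output frames",
            n_drop, len(labels),
        )
    keep = np.where(feasible)[0]
    chunks, valid, out_lens = chunks[keep], valid[keep], out_lens[keep]
    labels = [labels[i] for i in keep]
    if not labels:
        raise ValueError(
            "no feasible training chunks: every label exceeds its chunk's "
            "output frames (chunk_len / stem_stride too small for the data)"
        )

    opt = nn.AdamW(model.params(), lr=train_cfg.learning_rate,
                   beta1=train_cfg.beta1, beta2=train_cfg.beta2,
                   eps=train_cfg.epsilon, weight_decay=train_cfg.weight_decay)
    n = len(labels)
    steps = train_cfg.steps_per_epoch or max(1, n // train_cfg.batch_size)
    total_steps = steps * train_cfg.epochs
    history: list[dict] = []
    best_state, best_ident = None, -1.0
    step_no = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(steps):
            lo = (s * train_cfg.batch_size) % n
            idx = order[lo:lo + train_cfg.batch_size]
            if idx.size == 0:
                idx = order[:train_cfg.batch_size]
            batch = chunks[idx]
            lp = model.forward(batch, training=True)
            batch_losses, grad = ctc.ctc_loss_batch(
                lp, out_lens[idx], [labels[i] for i in idx]
            )
            finite = np.isfinite(batch_losses)
            norm = max(1, int(finite.sum()))
            losses.append(float(batch_losses[finite].mean()) if finite.any() else np.nan)
            opt.zero_grad()
            model.backward(grad / norm)
            if train_cfg.grad_clip > 0:
                total = math.sqrt(sum(float((p.grad ** 2).sum())
                                      for p in model.params()))
                if total > train_cfg.grad_clip:
                    for p in model.params():
                        p.grad *= train_cfg.grad_clip / total
            # linear warmup then cosine decay
            if step_no < train_cfg.warmup_steps:
                lr = train_cfg.learning_rate * (step_no + 1) / train_cfg.warmup_steps
            else:
                frac = (step_no - train_cfg.warmup_steps) / max(
                    1, total_steps - train_cfg.warmup_steps - 1)
                lr = train_cfg.learning_rate * (
                    train_cfg.lr_final_factor
                    + (1 - train_cfg.lr_final_factor)
                    * 0.5 * (1 + math.cos(math.pi * frac))
                )
            opt.step(lr=lr)
            step_no += 1
        val_ident = _median_identity(model, val_records, train_cfg.chunk_len) \
            if val_records else float("nan")
        entry = {"epoch": epoch, "loss": float(np.nanmean(losses)),
                 "val_identity": val_ident}
        history.append(entry)
        logger.info("epoch %d: loss %.4f, val identity %.4f",
                    epoch, entry["loss"], val_ident)
        if not val_records or (val_ident >= best_ident):
            best_ident = val_ident if val_records else 0.0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: LightCallModel, path: str | Path,
                    train_cfg: TrainConfig | None = None,
                    history: list[dict] | None = None) -> Path:
    """Write weights (.npz) plus a JSON sidecar describing the model."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **model.state_dict())
    sidecar = {
        "model_config": asdict(model.config),
        "train_config": asdict(train_cfg) if train_cfg else None,
        "parameter_count": count_parameters(model),
        "history": history,
    }
    side_path = path.with_suffix(path.suffix + ".json")
    side_path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> LightCallModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = ModelConfig(**sidecar["model_config"])
    model = build_model(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
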