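"""Two-stage temporal-convolutional sleep-stage network.

Stage 1 is a per-epoch encoder: a 1x1 stem, three inception-residual blocks
(parallel kernels 3/5/7 at a narrow branch width, 1x1 merge back to the
trunk, residual add), global average pooling, a linear embedding, and an
auxiliary 4-class head.  Stage 2 refines the epoch sequence: a dilated
temporal convolution network over the per-epoch embeddings concatenated
with the auxiliary probabilities — six residual blocks of two k=3 convs at
dilations 1..32 (receptive field of 253 epochs, i.e. over two hours of
context), a 1x1 projection and a 4-class head.

Both stages expose closed-form trainable-parameter counts; the default
widths are calibrated by integer search over that formula so the default
model reports 492,420 (stage 1), 538,796 (stage 2) and 1,031,216 (total)
parameters.  Class order is (W, Light, Deep, R); argmax ties break toward
the earlier class.  The 3- and 2-level outputs are deterministic collapses
of the 4-level posteriors: {Light, Deep} -> NREM and {Light, Deep, R} ->
Sleep, with W fixed under every collapse.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .nn import (Adam, Conv1d, Linear, ReLU, cross_entropy_with_logits,
                 softmax, softmax_backward)

logger = logging.getLogger(__name__)

CLASSES_4 = ("W", "Light", "Deep", "R")
CLASSES_3 = ("W", "NREM", "R")
CLASSES_2 = ("W", "Sleep")

COLLAPSE_4_TO_3 = {"W": "W", "Light": "NREM", "Deep": "NREM", "R": "R"}
COLLAPSE_4_TO_2 = {"W": "W", "Light": "Sleep", "Deep": "Sleep", "R": "Sleep"}

#: 5-class AASM reference -> 4-level model space.
FOUR_OF_FIVE = {"W": "W", "N1": "Light", "N2": "Light", "N3": "Deep", "R": "R"}


class CalibrationError(ValueError):
    """No integer widths reach the requested parameter counts exactly."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Stage1Config:
    kernel_sizes: tuple = (3, 5, 7)
    n_blocks: int = 3
    trunk_width: int = 200
    branch_width: int = 39
    embedding_dim: int = 333


@dataclass
class Stage2Config:
    dilations: tuple = (1, 2, 4, 8, 16, 32)
    width: int = 161
    bottleneck_width: int = 81
    head_width: int = 81


@dataclass
class TrainingConfig:
    epochs: int = 40
    learning_rate: float = 1e-3
    aux_weight: float = 0.3
    class_weights: tuple | None = None   # None -> inverse-frequency from data


@dataclass
class StagingConfig:
    n_input_channels: int = 9
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    width_multiplier: float = 1.0
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)

    #: fixed by the 4-level output space
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ValueError("the model's native output space is 4 classes")
        if self.receptive_field_epochs < 1:
            raise ValueError("stage-2 receptive field must cover >= 1 epoch")

    @property
    def receptive_field_epochs(self) -> int:
        return 1 + sum(4 * d for d in self.stage2.dilations)

    def effective(self) -> "StagingConfig":
        """Widths after applying ``width_multiplier`` (floors keep layers viable)."""
        m = self.width_multiplier
        if m == 1.0:
            return self
        s1 = replace(self.stage1,
                     trunk_width=max(6, round(self.stage1.trunk_width * m)),
                     branch_width=max(4, round(self.stage1.branch_width * m)),
                     embedding_dim=max(8, round(self.stage1.embedding_dim * m)))
        s2 = replace(self.stage2,
                     width=max(6, round(self.stage2.width * m)),
                     bottleneck_width=max(4, round(self.stage2.bottleneck_width * m)),
                     head_width=max(4, round(self.stage2.head_width * m)))
        return replace(self, stage1=s1, stage2=s2, width_multiplier=1.0)


# ---------------------------------------------------------------------------
# Closed-form parameter counts
# ---------------------------------------------------------------------------

def count_stage1_parameters(cfg: StagingConfig) -> int:
    """stem + n_blocks * (branches + merge) + embedding + aux head."""
    c = cfg.effective()
    s = c.stage1
    w, b, e = s.trunk_width, s.branch_width, s.embedding_dim
    stem = c.n_input_channels * w + w
    branches = sum(k * w * b + b for k in s.kernel_sizes)
    merge = len(s.kernel_sizes) * b * w + w
    embed = w * e + e
    aux = c.n_classes * e + c.n_classes
    return stem + s.n_blocks * (branches + merge) + embed + aux


def count_stage2_parameters(cfg: StagingConfig) -> int:
    """stem + blocks (two k=3 convs v->u->v each) + projection + head."""
    c = cfg.effective()
    e = c.stage1.embedding_dim
    s = c.stage2
    v, u, m = s.width, s.bottleneck_width, s.head_width
    c_in = e + c.n_classes
    stem = c_in * v + v
    block = (3 * v * u + u) + (3 * u * v + v)
    proj = v * m + m
    head = c.n_classes * m + c.n_classes
    return stem + len(s.dilations) * block + proj + head


def count_parameters(cfg: StagingConfig) -> tuple:
    s1 = count_stage1_parameters(cfg)
    s2 = count_stage2_parameters(cfg)
    return s1, s2, s1 + s2


def calibrate_widths(target_stage1: int = 492420, target_stage2: int = 538796,
                     n_input_channels: int = 9, kernel_sizes=(3, 5, 7),
                     n_blocks: int = 3, n_dilations: int = 6,
                     n_classes: int = 4) -> tuple:
    """Integer-search (trunk, branch, embedding, width, bottleneck, head)
    so the closed-form counts hit the targets exactly.

    Raises :class:`CalibrationError` listing the nearest achievable counts
    when no exact solution exists in the search box.
    """
    ksum = sum(kernel_sizes)
    nk = len(kernel_sizes)
    best_gap, best_counts = None, None
    stage1_hits = []
    for w in range(24, 301):
        for b in range(8, 2 * w):
            base = (n_input_channels * w + w
                    + n_blocks * (ksum * w * b + nk * b + nk * b * w + w))
            rem = target_stage1 - base - n_classes
            if rem <= 0:
                break
            if rem % (w + n_classes + 1) == 0:
                e = rem // (w + n_classes + 1)
                if 32 <= e <= 512:
                    stage1_hits.append((w, b, e))
            gap = abs(rem % (w + n_classes + 1))
            if best_gap is None or gap < best_gap:
                best_gap, best_counts = gap, (base + n_classes, target_stage2)
    for (w, b, e) in stage1_hits:
        for v in range(24, 321):
            base2 = e * v + (n_classes + 1) * v + n_classes
            for u in range(16, 2 * v):
                rem = target_stage2 - base2 - n_dilations * (6 * u * v + u + v)
                if rem <= 0:
                    break
                if rem % (v + n_classes + 1) == 0:
                    m = rem // (v + n_classes + 1)
                    if 16 <= m <= 2 * v:
                        return w, b, e, v, u, m
    raise CalibrationError(
        f"no exact integer widths for targets ({target_stage1}, "
        f"{target_stage2}); nearest achievable counts ~ {best_counts}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class _InceptionBlock:
    def __init__(self, w: int, b: int, kernels, rng):
        self.branches = [Conv1d(w, b, k, rng=rng) for k in kernels]
        self.acts = [ReLU() for _ in kernels]
        self.merge = Conv1d(len(kernels) * b, w, 1, rng=rng)
        self.out_act = ReLU()
        self.b = b

    @property
    def params(self):
        ps = []
        for c in self.branches:
            ps += c.params
        return ps + self.merge.params

    def forward(self, x):
        outs = [a.forward(c.forward(x)) for c, a in zip(self.branches, self.acts)]
        cat = np.concatenate(outs, axis=1)
        return self.out_act.forward(x + self.merge.forward(cat))

    def backward(self, dy):
        d = self.out_act.backward(dy)
        dcat = self.merge.backward(d)
        dx = d.copy()
        for i, (c, a) in enumerate(zip(self.branches, self.acts)):
            dx += c.backward(a.backward(dcat[:, i * self.b:(i + 1) * self.b]))
        return dx


class _Stage1Net:
    """Per-epoch encoder; input (N_epochs, C, L)."""

    def __init__(self, cfg: StagingConfig, rng):
        s = cfg.stage1
        self.stem = Conv1d(cfg.n_input_channels, s.trunk_width, 1, rng=rng)
        self.stem_act = ReLU()
        self.blocks = [_InceptionBlock(s.trunk_width, s.branch_width,
                                       s.kernel_sizes, rng)
                       for _ in range(s.n_blocks)]
        self.embed = Linear(s.trunk_width, s.embedding_dim, rng=rng)
        self.emb_act = ReLU()
        self.aux = Linear(s.embedding_dim, cfg.n_classes, rng=rng)

    @property
    def params(self):
        ps = self.stem.params[:]
        for b in self.blocks:
            ps += b.params
        return ps + self.embed.params + self.aux.params

    def forward(self, x):
        h = self.stem_act.forward(self.stem.forward(x))
        for b in self.blocks:
            h = b.forward(h)
        self._T = h.shape[2]
        g = h.mean(axis=2)                      # global average pool
        emb = self.emb_act.forward(self.embed.forward(g))
        aux_logits = self.aux.forward(emb)
        return emb, aux_logits

    def backward(self, d_emb, d_aux_logits):
        d_emb = d_emb + self.aux.backward(d_aux_logits)
        dg = self.embed.backward(self.emb_act.backward(d_emb))
        dh = np.repeat(dg[:, :, None], self._T, axis=2) / self._T
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.stem.backward(self.stem_act.backward(dh))


class _TcnBlock:
    def __init__(self, v: int, u: int, dilation: int, rng):
        self.c1 = Conv1d(v, u, 3, dilation=dilation, rng=rng)
        self.a1 = ReLU()
        self.c2 = Conv1d(u, v, 3, dilation=dilation, rng=rng)
        self.out_act = ReLU()

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x):
        return self.out_act.forward(
            x + self.c2.forward(self.a1.forward(self.c1.forward(x))))

    def backward(self, dy):
        d = self.out_act.backward(dy)
        return d + self.c1.backward(self.a1.backward(self.c2.backward(d)))


class _Stage2Net:
    """Sequence refiner; input (1, embedding+n_classes, T_epochs)."""

    def __init__(self, cfg: StagingConfig, rng):
        s = cfg.stage2
        c_in = cfg.stage1.embedding_dim + cfg.n_classes
        self.stem = Conv1d(c_in, s.width, 1, rng=rng)
        self.stem_act = ReLU()
        self.blocks = [_TcnBlock(s.width, s.bottleneck_width, d, rng)
                       for d in s.dilations]
        self.proj = Conv1d(s.width, s.head_width, 1, rng=rng)
        self.proj_act = ReLU()
        self.head = Conv1d(s.head_width, cfg.n_classes, 1, rng=rng)

    @property
    def params(self):
        ps = self.stem.params[:]
        for b in self.blocks:
            ps += b.params
        return ps + self.proj.params + self.head.params

    def forward(self, z):
        h = self.stem_act.forward(self.stem.forward(z))
        for b in self.blocks:
            h = b.forward(h)
        return self.head.forward(self.proj_act.forward(self.proj.forward(h)))

    def backward(self, dlogits):
        dh = self.proj.backward(self.proj_act.backward(
            self.head.backward(dlogits)))
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        return self.stem.backward(self.stem_act.backward(dh))


# ---------------------------------------------------------------------------
# Model container and operations
# ---------------------------------------------------------------------------

@dataclass
class StagingModel:
    config: StagingConfig
    stage1: _Stage1Net
    stage2: _Stage2Net
    param_count_stage1: int
    param_count_stage2: int
    param_count_total: int
    trained: bool = False
    history: list = field(default_factory=list)

    @property
    def params(self):
        return self.stage1.params + self.stage2.params

    def enumerate_parameter_count(self) -> tuple:
        """Brute-force count by walking every weight tensor."""
        s1 = sum(p.v.size for p in self.stage1.params)
        s2 = sum(p.v.size for p in self.stage2.params)
        return s1, s2, s1 + s2

    def forward(self, x: np.ndarray):
        """x: (T_epochs, C, L) -> (probs4 (T,4), aux_logits, seq_logits)."""
        emb, aux_logits = self.stage1.forward(x)
        aux_p = softmax(aux_logits, axis=1)
        self._aux_p = aux_p
        z = np.concatenate([emb, aux_p], axis=1).T[None, :, :]
        seq_logits = self.stage2.forward(z)[0].T      # (T, 4)
        return softmax(seq_logits, axis=1), aux_logits, seq_logits


@dataclass
class StagePredictions:
    """Per-epoch 4-level posteriors with hierarchical label views."""

    probs4: np.ndarray                    # (n_epochs, 4), rows sum to 1
    qc_rejected: np.ndarray | None = None # carried alongside, never masking

    def __post_init__(self) -> None:
        self.probs4 = np.asarray(self.probs4, dtype=float)
        if np.max(np.abs(self.probs4.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("probs4 rows must sum to 1 within 1e-6")

    def __len__(self) -> int:
        return self.probs4.shape[0]

    @property
    def label4(self) -> tuple:
        return tuple(CLASSES_4[i] for i in np.argmax(self.probs4, axis=1))

    @property
    def label3(self) -> tuple:
        return collapse_predictions(self, 3)[0]

    @property
    def label2(self) -> tuple:
        return collapse_predictions(self, 2)[0]


def build_model(cfg: StagingConfig | None = None) -> StagingModel:
    """Instantiate the network; initialization is a pure function of
    (config, seed), so identical configs yield bit-identical weights."""
    cfg = cfg or StagingConfig()
    eff = cfg.effective()
    rng = np.random.default_rng(cfg.seed)
    stage1 = _Stage1Net(eff, rng)
    stage2 = _Stage2Net(eff, rng)
    s1, s2, tot = count_parameters(eff)
    model = StagingModel(config=cfg, stage1=stage1, stage2=stage2,
                         param_count_stage1=s1, param_count_stage2=s2,
                         param_count_total=tot)
    actual = model.enumerate_parameter_count()
    if actual != (s1, s2, tot):  # formula and tensors must agree
        raise RuntimeError(f"count formula {s1, s2, tot} != tensors {actual}")
    return model


@dataclass
class TrainingExample:
    subject_id: str
    inputs: np.ndarray       # (T, C, L)
    labels4: np.ndarray      # (T,) ints into CLASSES_4


def make_examples(subjects: Sequence, rate_hz: float = 4.0,
                  context_epochs: int = 0) -> list:
    """Run the RR -> tachogram -> features -> tensor pipeline for cohort
    subjects carrying beat-time series, pairing tensors with 4-level labels."""
    from .features import assemble_inputs, compute_epoch_features
    from .io_formats import EpochGrid
    from .rr_processing import clean_rr, resample_tachogram

    out = []
    for s in subjects:
        if s.rr is None:
            raise ValueError(f"subject {s.meta.subject_id} has no RR series")
        tach = resample_tachogram(clean_rr(s.rr), rate_hz)
        grid = EpochGrid(n_epochs=len(s.hypnogram),
                         start_time=s.hypnogram.start_time)
        feats = compute_epoch_features(tach, grid)
        tensor = assemble_inputs(tach, feats, context_epochs)
        labels = np.array([CLASSES_4.index(FOUR_OF_FIVE[l])
                           for l in s.hypnogram.labels])
        out.append(TrainingExample(subject_id=s.meta.subject_id,
                                   inputs=tensor.data, labels4=labels))
    return out


def participant_split(ids: Sequence[str], split_seed: int,
                      test_fraction: float = 0.2) -> tuple:
    """Random 80/20 split at the participant level."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(split_seed)
    order = list(rng.permutation(len(ids)))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = {ids[i] for i in order[:n_test]}
    train = {i for i in ids if i not in test}
    if train & test:
        raise RuntimeError("subject appears in both splits")
    return train, test


def _snapshot(model: StagingModel) -> list:
    return [p.v.copy() for p in model.params]


def _restore(model: StagingModel, weights: list) -> None:
    for p, w in zip(model.params, weights):
        p.v[...] = w


def train_model(model: StagingModel, cohort: Sequence[TrainingExample],
                split_seed: int = 0) -> StagingModel:
    """Train with a participant-level 80/20 split, retaining the weights
    with the smallest held-out error.  ``model.history`` records the
    train/test accuracy trajectory."""
    if len(cohort) < 5:
        raise ValueError("need >= 5 subjects for a non-degenerate 80/20 split")
    tcfg = model.config.training
    train_ids, test_ids = participant_split(
        [ex.subject_id for ex in cohort], split_seed)
    train_set = [ex for ex in cohort if ex.subject_id in train_ids]
    test_set = [ex for ex in cohort if ex.subject_id in test_ids]

    if tcfg.class_weights is not None:
        cw = np.asarray(tcfg.class_weights, dtype=float)
    else:
        counts = np.bincount(
            np.concatenate([ex.labels4 for ex in train_set]), minlength=4)
        cw = counts.sum() / np.maximum(counts, 1) / 4.0

    opt = Adam(model.params, lr=tcfg.learning_rate)
    rng = np.random.default_rng(split_seed + 1)
    best_err, best_w = np.inf, _snapshot(model)

    def accuracy(examples):
        hits = tot = 0
        for ex in examples:
            probs, _, _ = model.forward(ex.inputs)
            hits += int(np.sum(np.argmax(probs, axis=1) == ex.labels4))
            tot += ex.labels4.size
        return hits / max(1, tot)

    for it in range(tcfg.epochs):
        for ex in [train_set[i] for i in rng.permutation(len(train_set))]:
            opt.zero_grad()
            probs, aux_logits, seq_logits = model.forward(ex.inputs)
            loss, dseq = cross_entropy_with_logits(seq_logits, ex.labels4, cw)
            aux_loss, daux = cross_entropy_with_logits(aux_logits, ex.labels4, cw)
            daux = daux * tcfg.aux_weight
            e_dim = model.config.effective().stage1.embedding_dim
            # stage-2 input gradient, split into embedding and aux-posterior
            # channels; the latter flows through the softmax Jacobian
            dz = model.stage2.backward(dseq.T[None, :, :])[0].T  # (T, e+4)
            d_aux_from_seq = softmax_backward(model._aux_p, dz[:, e_dim:], axis=1)
            model.stage1.backward(dz[:, :e_dim], daux + d_aux_from_seq)
            opt.step()
        tr_acc, te_acc = accuracy(train_set), accuracy(test_set)
        model.history.append({"iteration": it, "train_accuracy": tr_acc,
                              "test_accuracy": te_acc})
        if 1.0 - te_acc < best_err:
            best_err = 1.0 - te_acc
            best_w = _snapshot(model)
    _restore(model, best_w)
    model.trained = True
    logger.info("training done: best held-out accuracy %.3f", 1.0 - best_err)
    return model


def predict_stages(model: StagingModel, inputs, qc=None,
                   allow_untrained: bool = False) -> StagePredictions:
    """Score every epoch of a recording, including QC-rejected epochs;
    rejection flags are carried on the result, never used to mask."""
    if not model.trained and not allow_untrained:
        raise RuntimeError("model is untrained; pass allow_untrained=True "
                           "to score anyway")
    x = inputs.data if hasattr(inputs, "data") else np.asarray(inputs)
    if x.ndim != 3 or x.shape[1] != model.config.n_input_channels:
        raise ValueError(
            f"input shape {x.shape} incompatible with "
            f"{model.config.n_input_channels} channels")
    probs, _, _ = model.forward(x)
    rej = None
    if qc is not None:
        rej = np.asarray(qc.epoch_rejected, dtype=bool)[:probs.shape[0]]
    return StagePredictions(probs4=probs, qc_rejected=rej)


def collapse_predictions(p: StagePredictions, level: int) -> tuple:
    """Collapse 4-level posteriors to the requested level.

    Probabilities are summed within collapsed groups and labels recomputed
    as the argmax of the collapsed posterior (which can differ from
    collapsing the 4-level argmax).  Returns (labels, probs)."""
    if level == 4:
        return tuple(CLASSES_4[i] for i in np.argmax(p.probs4, axis=1)), p.probs4
    if level == 3:
        classes, cmap = CLASSES_3, COLLAPSE_4_TO_3
    elif level == 2:
        classes, cmap = CLASSES_2, COLLAPSE_4_TO_2
    else:
        raise ValueError(f"unknown level {level}; expected 2, 3 or 4")
    probs = np.zeros((p.probs4.shape[0], len(classes)))
    for i4, c4 in enumerate(CLASSES_4):
        probs[:, classes.index(cmap[c4])] += p.probs4[:, i4]
    labels = tuple(classes[i] for i in np.argmax(probs, axis=1))
    return labels, probs


def collapse_labels(labels4: Sequence[str], level: int) -> tuple:
    """Collapse hard 4-level labels (used for references and fixtures)."""
    if level == 4:
        return tuple(labels4)
    cmap = {3: COLLAPSE_4_TO_3, 2: COLLAPSE_4_TO_2}[level]
    return tuple(cmap[l] for l in labels4)
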