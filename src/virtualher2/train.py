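"""Adversarial training of the virtual staining network.

Follows a patient-aware protocol: whole-slide tiles are split by patient
into train/validation/test sets (~80/10/10 by tile count, patients never
straddle splits), 256-px crops are drawn at random from 1024-px tiles
(64-px crops from smaller synthetic tiles), and the generator and
discriminator are optimized alternately with AdamW at learning rates 1e-4
and 1e-5 and a 2:1 generator:discriminator update frequency.

A *step* is one optimizer update; the 2:1 schedule interleaves updates as
G, G, D, G, G, D, ...  Model selection uses the checkpoint with the lowest
validation MSE computed on full validation tiles.

The public surface is a statsmodels-style pair: build a
:class:`VirtualStainingModel` from tile records, call ``fit()``, and
inspect the returned :class:`VirtualStainingResults` (checkpoints,
histories, batch manifests, ``summary()``) or use it to stain new tiles.
"""

from __future__ import annotations

import ctypes
import sys
from dataclasses import dataclass, field

import numpy as np

from .network import (
    DiscriminatorConfig,
    GeneratorConfig,
    LossWeights,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generator_loss,
)
from .nn import AdamW, Tensor, no_grad
from .types import SyntheticPair, TilePair


def _tune_allocator() -> None:
    """Keep large temporaries on the heap free-list (glibc only)."""
    if sys.platform.startswith("linux"):
        try:
            ctypes.CDLL("libc.so.6").mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        except OSError:  # pragma: no cover
            pass


@dataclass
class TileRecord:
    """One training example: a registered AF stack / brightfield pair."""

    patient_id: str
    tile_id: str
    af: np.ndarray  # (4, h, w)
    target: np.ndarray  # (h, w, 3)


def records_from_pairs(pairs, tiles_per_patient: int = 4) -> list[TileRecord]:
    """Adapt synthetic or registered tile pairs into training records."""
    from .synth import patient_id_for

    records = []
    for i, p in enumerate(pairs):
        if isinstance(p, SyntheticPair):
            pid = patient_id_for(p, tiles_per_patient)
            records.append(TileRecord(pid, f"{pid}/t{p.seed}", p.af, p.ihc))
        elif isinstance(p, TilePair):
            records.append(
                TileRecord(p.patient_id, p.tile_id or f"tile{i}", p.af, p.target)
            )
        else:
            raise TypeError(f"unsupported pair type: {type(p)!r}")
    return records


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset

    def __post_init__(self):
        if (
            self.train_ids & self.val_ids
            or self.train_ids & self.test_ids
            or self.val_ids & self.test_ids
        ):
            raise ValueError("patient sets must be disjoint")


def split_by_patient(
    records: list[TileRecord],
    fractions: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Patient-disjoint train/val/test split at approximate tile fractions."""
    by_patient: dict[str, list] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    patients = sorted(by_patient)
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to build three splits")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    total = len(records)
    target_test = fractions[2] * total
    target_val = fractions[1] * total

    test_p, val_p, train_p = [], [], []
    n_test = n_val = 0
    for pid in order:
        n = len(by_patient[pid])
        if n_test < target_test and len(order) - len(test_p) > 2:
            test_p.append(pid)
            n_test += n
        elif n_val < target_val and len(order) - len(test_p) - len(val_p) > 1:
            val_p.append(pid)
            n_val += n
        else:
            train_p.append(pid)
    if not train_p:  # pragma: no cover - tiny pathological inputs
        train_p.append(val_p.pop() if val_p else test_p.pop())
    pick = lambda ps: [r for p in ps for r in by_patient[p]]
    return DatasetSplit(
        train=pick(train_p),
        val=pick(val_p),
        test=pick(test_p),
        train_ids=frozenset(train_p),
        val_ids=frozenset(val_p),
        test_ids=frozenset(test_p),
    )


def sample_crops(
    record, crop: int, n: int, seed: int = 0, augment: bool = False
) -> list[tuple]:
    """Draw co-located (AF, target) crops from one tile pair.

    Optional augmentation applies an identical flip/rot90 to both crops.
    """
    af = record.af if hasattr(record, "af") else record[0]
    target = record.target if hasattr(record, "target") else record[1]
    h, w = af.shape[-2:]
    if crop > h or crop > w:
        raise ValueError("crop exceeds tile size")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        r = int(rng.integers(0, h - crop + 1))
        c = int(rng.integers(0, w - crop + 1))
        a = af[:, r : r + crop, c : c + crop]
        t = target[r : r + crop, c : c + crop]
        if augment:
            k = int(rng.integers(4))
            flip = bool(rng.integers(2))
            a = np.rot90(a, k, axes=(1, 2))
            t = np.rot90(t, k, axes=(0, 1))
            if flip:
                a = a[:, :, ::-1]
                t = t[:, ::-1]
        out.append((np.ascontiguousarray(a), np.ascontiguousarray(t)))
    return out


@dataclass(frozen=True)
class TrainConfig:
    crop: int = 256
    batch: int = 28
    lr_g: float = 1e-4
    lr_d: float = 1e-5
    weight_decay: float = 1e-5
    g_d_ratio: tuple = (2, 1)
    max_steps: int = 2000
    seed: int = 0
    checkpoint_every: int = 250
    augment: bool = False
    max_val_tiles: int = 4

    def __post_init__(self):
        if self.batch < 1 or self.crop < 16:
            raise ValueError("batch must be >= 1 and crop >= 16")
        if min(self.g_d_ratio) < 1:
            raise ValueError("update ratio entries must be positive integers")


@dataclass
class Checkpoint:
    step: int
    g_updates: int
    gen_state: list
    disc_state: list
    val_mse: float


def select_best(checkpoints: list[Checkpoint]) -> Checkpoint:
    """Checkpoint with minimal validation MSE; ties resolve to the earliest."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    return min(checkpoints, key=lambda c: (c.val_mse, c.step))


class ChannelNormalizer:
    """Per-channel affine normalization from robust intensity percentiles."""

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = np.asarray(lo, dtype=np.float32)
        self.hi = np.asarray(hi, dtype=np.float32)

    @classmethod
    def from_records(cls, records, p_lo: float = 0.1, p_hi: float = 99.9):
        stacks = np.stack([r.af for r in records])  # (n, 4, h, w)
        lo = np.percentile(stacks, p_lo, axis=(0, 2, 3))
        hi = np.percentile(stacks, p_hi, axis=(0, 2, 3))
        hi = np.maximum(hi, lo + 1e-6)
        return cls(lo, hi)

    def __call__(self, af: np.ndarray) -> np.ndarray:
        lo = self.lo.reshape(-1, 1, 1)
        hi = self.hi.reshape(-1, 1, 1)
        return np.clip((af - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


class VirtualStainingModel:
    """Conditional GAN virtual staining model bound to a dataset split.

    Parameters
    ----------
    records : list of TileRecord (or objects accepted by records_from_pairs)
    gen_cfg, disc_cfg, loss_weights, train_cfg : configuration dataclasses;
        defaults reproduce the full-scale architecture and schedule.
    split : optional precomputed DatasetSplit; otherwise a patient-wise
        80/10/10 split is drawn with the training seed.
    """

    def __init__(
        self,
        records,
        gen_cfg: GeneratorConfig | None = None,
        disc_cfg: DiscriminatorConfig | None = None,
        loss_weights: LossWeights | None = None,
        train_cfg: TrainConfig | None = None,
        split: DatasetSplit | None = None,
    ):
        if records and not isinstance(records[0], TileRecord):
            records = records_from_pairs(records)
        self.records = records
        self.gen_cfg = gen_cfg or GeneratorConfig()
        self.disc_cfg = disc_cfg or DiscriminatorConfig()
        self.loss_weights = loss_weights or LossWeights()
        self.train_cfg = train_cfg or TrainConfig()
        self.split = split or split_by_patient(records, seed=self.train_cfg.seed)
        if not self.split.train or not self.split.val:
            raise ValueError("training and validation splits must be non-empty")

    # -- internals --------------------------------------------------------
    def _batch(self, rng, generator_batch: bool):
        cfg = self.train_cfg
        xs, ys, ids = [], [], []
        train = self.split.train
        for _ in range(cfg.batch):
            rec = train[int(rng.integers(len(train)))]
            (a, t) = sample_crops(
                rec, cfg.crop, 1, seed=int(rng.integers(2**31)), augment=cfg.augment
            )[0]
            xs.append(a.transpose(1, 2, 0))
            ys.append(t)
            ids.append(rec.tile_id)
        x = np.stack(xs).astype(np.float32)
        y = np.stack(ys).astype(np.float32)
        return x, y, ids

    def _val_mse(self, gen, normalizer=None) -> float:
        tiles = self.split.val[: self.train_cfg.max_val_tiles]
        errs = []
        with no_grad():
            for rec in tiles:
                af = rec.af if normalizer is None else normalizer(rec.af)
                out = gen(af.transpose(1, 2, 0)[None].astype(np.float32))
                errs.append(float(np.mean((out.data[0] - rec.target) ** 2)))
        return float(np.mean(errs))

    # -- estimation -------------------------------------------------------
    def fit(self, callback=None) -> "VirtualStainingResults":
        _tune_allocator()
        cfg = self.train_cfg
        rng = np.random.default_rng(cfg.seed)
        gen = build_generator(self.gen_cfg, seed=cfg.seed)
        disc = build_discriminator(self.disc_cfg, seed=cfg.seed + 1)
        opt_g = AdamW(gen.parameters(), cfg.lr_g, weight_decay=cfg.weight_decay)
        opt_d = AdamW(disc.parameters(), cfg.lr_d, weight_decay=cfg.weight_decay)
        normalizer = ChannelNormalizer.from_records(self.split.train)

        n_g, n_d = cfg.g_d_ratio
        schedule = ["G"] * n_g + ["D"] * n_d
        checkpoints: list[Checkpoint] = []
        g_hist: list[float] = []
        d_hist: list[float] = []
        manifests: list[tuple] = []
        g_updates = d_updates = 0
        last_fake = last_real = None

        for step in range(1, cfg.max_steps + 1):
            role = schedule[(step - 1) % len(schedule)]
            if role == "G":
                x, y, ids = self._batch(rng, True)
                x = np.stack([normalizer(a.transpose(2, 0, 1)).transpose(1, 2, 0) for a in x])
                out = gen(x)
                d_logit = disc(out)
                loss = generator_loss(out, Tensor(y), d_logit, self.loss_weights)
                opt_g.zero_grad()
                loss.backward()
                opt_g.step()
                g_updates += 1
                g_hist.append(float(loss.data))
                manifests.append((step, "G", tuple(ids)))
                last_fake, last_real = out.data.copy(), y
            else:
                if last_fake is None:  # pragma: no cover - G always leads
                    continue
                logit_fake = disc(Tensor(last_fake))
                logit_real = disc(Tensor(last_real))
                loss = discriminator_loss(logit_fake, logit_real)
                opt_d.zero_grad()
                loss.backward()
                opt_d.step()
                d_updates += 1
                d_hist.append(float(loss.data))
            if not np.isfinite(float(loss.data)):
                raise FloatingPointError(f"non-finite loss at step {step}")
            if step % cfg.checkpoint_every == 0 or step == cfg.max_steps:
                val = self._val_mse(gen, normalizer)
                checkpoints.append(
                    Checkpoint(step, g_updates, gen.state_dict(), disc.state_dict(), val)
                )
                if callback is not None:
                    callback(step, val)

        best = select_best(checkpoints)
        gen.load_state_dict(best.gen_state)
        return VirtualStainingResults(
            model=self,
            generator=gen,
            normalizer=normalizer,
            checkpoints=checkpoints,
            best_checkpoint=best,
            g_loss_history=g_hist,
            d_loss_history=d_hist,
            batch_manifests=manifests,
            g_updates=g_updates,
            d_updates=d_updates,
        )


def fit(
    split: DatasetSplit,
    gen_cfg: GeneratorConfig | None = None,
    disc_cfg: DiscriminatorConfig | None = None,
    loss_weights: LossWeights | None = None,
    train_cfg: TrainConfig | None = None,
) -> list[Checkpoint]:
    """Functional wrapper: train on a precomputed split, return checkpoints."""
    records = split.train + split.val + split.test
    model = VirtualStainingModel(
        records, gen_cfg, disc_cfg, loss_weights, train_cfg, split=split
    )
    return model.fit().checkpoints


@dataclass
class VirtualStainingResults:
    """Fitted virtual staining model with training diagnostics."""

    model: VirtualStainingModel
    generator: object
    normalizer: ChannelNormalizer
    checkpoints: list
    best_checkpoint: Checkpoint
    g_loss_history: list
    d_loss_history: list
    batch_manifests: list
    g_updates: int
    d_updates: int

    @property
    def val_mse_history(self) -> list:
        return [(c.step, c.val_mse) for c in self.checkpoints]

    def stain(self, af: np.ndarray) -> np.ndarray:
        """Virtually stain a (4, H, W) AF stack -> (H, W, 3) in [0, 1]."""
        x = self.normalizer(np.asarray(af, dtype=np.float32))
        out = self.generator.infer(x)
        return np.clip(out.transpose(1, 2, 0), 0.0, 1.0)

    def training_tile_ids(self) -> set:
        return {tid for _, role, ids in self.batch_manifests for tid in ids}

    def assert_no_leakage(self) -> None:
        """Verify no test-patient tile ever entered a training batch."""
        test_tiles = {r.tile_id for r in self.model.split.test}
        used = self.training_tile_ids()
        leaked = test_tiles & used
        if leaked:
            raise AssertionError(f"test tiles leaked into training: {sorted(leaked)}")

    def summary(self) -> str:
        best = self.best_checkpoint
        lines = [
            "Virtual HER2 staining results",
            "=============================",
            f"generator parameters:      {self.generator.parameter_count():>12,d}",
            f"train/val/test tiles:      {len(self.model.split.train)}/"
            f"{len(self.model.split.val)}/{len(self.model.split.test)}",
            f"generator updates:         {self.g_updates}",
            f"discriminator updates:     {self.d_updates}",
            f"final generator loss:      {self.g_loss_history[-1]:.4f}",
            f"best validation MSE:       {best.val_mse:.5f} (step {best.step})",
        ]
        return "\n".join(lines)

    def plot_losses(self, ax=None):
        """Plot generator/discriminator loss histories (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.g_loss_history, label="generator")
        x_d = np.linspace(0, len(self.g_loss_history), num=len(self.d_loss_history))
        ax.plot(x_d, self.d_loss_history, label="discriminator")
        ax.set_xlabel("generator update")
        ax.set_ylabel("loss")
        ax.legend()
        return ax
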