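"""Two-phase training, inference and evaluation.

Phase 1 jointly optimises SINet and IENet with the composite dual-domain
objective (sinogram fidelity + image fidelity + cross-domain consistency +
the high-frequency residual regulariser).  Phase 2 freezes the stage-1
cascade, precomputes its outputs and their Sobel edge maps, and trains the
edge-conditioned refinement generator against a WGAN-GP critic.

Reproducibility contract: (config, seed, dataset) determine every logged
number — the master seed fans out to parameter initialisation, batch
shuffling and the gradient-penalty interpolation draws.

Two scale presets are provided.  ``paper`` keeps the published acquisition
(736 detectors, 720/180/60 views, 256 px); ``desk`` is a proportionally
reduced configuration (180 detectors, 180/60/20 views, 64 px, narrower
networks) sized so the full two-phase pipeline trains in minutes on one CPU
core while still exhibiting sparse-view streaks and their removal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .geometry import CTImage, FanBeamGeometry, FanBeamProjector, Sinogram
from .losses import (LossWeights, consistency_loss, ddpm_loss, hf_regularizer,
                     l1, mse, sobel_edges, wgan_objectives)
from .metrics import MetricsTable, evaluate_pair, psnr
from .models import Discriminator, DualDomainModel, HENet, IENet, SINet
from .phantom import PhantomDataset

__all__ = ["TrainConfig", "train_ddpm", "train_gan", "reconstruct", "evaluate",
           "build_stage1", "build_stage2", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Everything that determines a training run.

    Optimiser settings follow the published recipe: Adam with betas
    (0.9, 0.999) for phase 1 and (0.5, 0.9) for the adversarial phase,
    learning rate decaying exponentially from 1e-3 to 1e-5 over the
    configured epochs, batch size 2.
    """

    geometry: FanBeamGeometry = field(default_factory=FanBeamGeometry)
    weights: LossWeights = field(default_factory=LossWeights)
    image_size: int = 256
    depth: int = 4
    base_width: int = 64
    n_primitives: int = 96
    reduction: int = 16
    critic_widths: tuple = (64, 64, 128, 128, 256, 512)
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    phase1_betas: tuple = (0.9, 0.999)
    phase2_betas: tuple = (0.5, 0.9)
    batch_size: int = 2
    epochs: int = 30
    max_steps: int | None = None
    critic_steps_per_gen: int = 5
    gan_epochs: int = 1
    max_gen_steps: int | None = None
    val_fraction: float = 0.1
    filter_name: str = "cosine"
    freeze_ddpm: bool = True
    train_dtype: str = "float32"
    seed: int = 0
    scale_preset: str = "paper"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        geom = FanBeamGeometry(n_detectors=180, n_views_standard=180,
                               n_views_intermediate=60, n_views_sparse=20)
        base = dict(geometry=geom, image_size=64, depth=2, base_width=16,
                    n_primitives=16, critic_widths=(16, 16, 32, 32),
                    epochs=2, gan_epochs=1, scale_preset="desk")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper(cls, **overrides) -> "TrainConfig":
        return cls(**overrides)

    def lr_at(self, epoch: int) -> float:
        if self.epochs == 1:
            return self.lr_start
        frac = epoch / (self.epochs - 1)
        return float(self.lr_start * (self.lr_end / self.lr_start) ** frac)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["weights"] = asdict(self.weights)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["geometry"] = FanBeamGeometry.from_dict(d["geometry"])
        d["weights"] = LossWeights(**d["weights"])
        for k in ("critic_widths", "phase1_betas", "phase2_betas"):
            d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# model construction and checkpoints
# ---------------------------------------------------------------------------

def _dtype(config):
    return np.float32 if config.train_dtype == "float32" else np.float64


def build_stage1(config: TrainConfig, rng=None):
    """SINet + IENet + intermediate-view projector, per config."""
    rng = rng or np.random.default_rng(config.seed)
    g = config.geometry
    dt = _dtype(config)
    proj = FanBeamProjector(g, g.view_angles(g.n_views_intermediate),
                            config.image_size, filter_name=config.filter_name)
    sinet = SINet(rng, g.n_views_sparse, g.n_views_intermediate, g.n_detectors,
                  depth=config.depth, base_width=config.base_width,
                  n_primitives=config.n_primitives, dtype=dt)
    ienet = IENet(rng, depth=config.depth, base_width=config.base_width,
                  n_primitives=config.n_primitives, dtype=dt)
    return DualDomainModel(sinet, ienet, proj)


def build_stage2(config: TrainConfig, rng=None):
    """HENet + critic, per config."""
    rng = rng or np.random.default_rng(config.seed + 1)
    dt = _dtype(config)
    henet = HENet(rng, depth=config.depth, base_width=config.base_width,
                  n_primitives=config.n_primitives, dtype=dt)
    critic = Discriminator(rng, config.image_size,
                           widths=config.critic_widths, dtype=dt)
    return henet, critic


def save_checkpoint(path, modules: dict, config: TrainConfig,
                    extra: dict | None = None):
    """Single-container checkpoint: all parameter arrays + config hash."""
    arrays = {}
    for name, mod in modules.items():
        for k, v in mod.state_dict().items():
            arrays[f"{name}/{k}"] = v
    meta = {"config": config.to_dict(), "config_hash": config.hash(),
            "modules": sorted(modules), **(extra or {})}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Returns (config, {module: state_dict}, meta)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        states = {m: {} for m in meta["modules"]}
        for k in z.files:
            if k == "__meta__":
                continue
            mod, pname = k.split("/", 1)
            states[mod][pname] = z[k]
    config = TrainConfig.from_dict(meta["config"])
    if config.hash() != meta["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    return config, states, meta


# ---------------------------------------------------------------------------
# phase 1: dual-domain training
# ---------------------------------------------------------------------------

def _case_arrays(dataset, names, dtype):
    x = np.stack([dataset[n]["sparse_sino"] for n in names]).astype(dtype)
    xl = np.stack([dataset[n]["inter_sino"] for n in names]).astype(dtype)
    yl = np.stack([dataset[n]["full_image"] for n in names]).astype(dtype)
    return x, xl, yl


def _val_psnr(model, dataset, names, data_range=1.0):
    vals = []
    for n in names:
        rec = model.reconstruct(dataset[n]["sparse_sino"].astype(
            model.sinet._dtype))
        vals.append(psnr(rec, dataset[n]["full_image"], data_range))
    return float(np.mean(vals))


def train_ddpm(dataset: PhantomDataset, config: TrainConfig,
               checkpoint_path=None):
    """Jointly train SINet + IENet with the composite dual-domain loss.

    Returns ``(model, history)``; ``history`` is a list of per-step dicts
    (total plus the four components) followed by per-epoch validation
    entries.  The best-validation parameter set is restored at the end and
    written to ``checkpoint_path`` when given.
    """
    if len(dataset.train_cases) == 0:
        raise ValueError("empty training dataset")
    ss = np.random.SeedSequence(config.seed)
    s_init, s_shuffle = ss.spawn(2)
    model = build_stage1(config, np.random.default_rng(s_init))
    dt = _dtype(config)

    names = list(dataset.train_cases)
    n_val = max(1, int(round(config.val_fraction * len(names)))) \
        if len(names) > 1 else 0
    val_names = names[len(names) - n_val:]
    train_names = names[:len(names) - n_val] or names

    params = model.parameters()
    opt = Adam(params, lr=config.lr_start, betas=config.phase1_betas)
    shuffle_rng = np.random.default_rng(s_shuffle)
    history = []
    step = 0
    best = (-np.inf, None)
    stop = False
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = shuffle_rng.permutation(len(train_names))
        for i0 in range(0, len(order), config.batch_size):
            batch = [train_names[j] for j in order[i0:i0 + config.batch_size]]
            x, xl, yl = _case_arrays(dataset, batch, dt)
            out = model(x)
            total, comps = ddpm_loss(out.x_prime, xl, out.y_prime, yl,
                                     config.weights, projector=model.projector)
            opt.zero_grad()
            total.backward()
            opt.step()
            step += 1
            history.append({"phase": 1, "epoch": epoch, "step": step,
                            "total": float(total.item()), **comps,
                            "lr": opt.lr})
            if config.max_steps is not None and step >= config.max_steps:
                stop = True
                break
        if val_names:
            v = _val_psnr(model, dataset, val_names)
            history.append({"phase": 1, "epoch": epoch, "val_psnr": v})
            if v > best[0]:
                best = (v, {"sinet": model.sinet.state_dict(),
                            "ienet": model.ienet.state_dict()})
        if stop:
            break
    if best[1] is not None:
        model.sinet.load_state_dict(best[1]["sinet"])
        model.ienet.load_state_dict(best[1]["ienet"])
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path,
                        {"sinet": model.sinet, "ienet": model.ienet},
                        config, extra={"phase": 1})
    return model, history


# ---------------------------------------------------------------------------
# phase 2: adversarial refinement
# ---------------------------------------------------------------------------

def _stage1_outputs(model, dataset, names, dtype):
    """Frozen stage-1 predictions and their edge maps for all cases."""
    yp, bb = [], []
    for n in names:
        y = model.reconstruct(dataset[n]["sparse_sino"].astype(dtype))
        yp.append(y)
        bb.append(sobel_edges(y))
    return np.stack(yp).astype(dtype), np.stack(bb).astype(dtype)


def train_gan(dataset: PhantomDataset, ddpm_checkpoint, config: TrainConfig,
              checkpoint_path=None):
    """Train HENet against the WGAN-GP critic on frozen stage-1 outputs.

    ``ddpm_checkpoint`` is a path or an in-memory ``DualDomainModel``.
    Alternates ``critic_steps_per_gen`` critic updates with one generator
    update.  Returns ``(henet, critic, history)``.
    """
    if isinstance(ddpm_checkpoint, DualDomainModel):
        model = ddpm_checkpoint
        cfg1 = config
    else:
        p = Path(ddpm_checkpoint)
        if not p.exists():
            raise FileNotFoundError(f"missing phase-1 checkpoint {p}")
        cfg1, states, _ = load_checkpoint(p)
        model = build_stage1(cfg1)
        model.sinet.load_state_dict(states["sinet"])
        model.ienet.load_state_dict(states["ienet"])

    ss = np.random.SeedSequence(config.seed + 17)
    s_init, s_shuffle, s_eps = ss.spawn(3)
    henet, critic = build_stage2(config, np.random.default_rng(s_init))
    dt = _dtype(config)

    names = list(dataset.train_cases)
    yp_all, b_all = _stage1_outputs(model, dataset, names, dt)
    yl_all = np.stack([dataset[n]["full_image"] for n in names]).astype(dt)
    xl_all = np.stack([dataset[n]["inter_sino"] for n in names]).astype(dt)

    g_opt = Adam(henet.parameters(), lr=config.lr_start,
                 betas=config.phase2_betas)
    d_opt = Adam(critic.parameters(), lr=config.lr_start,
                 betas=config.phase2_betas)
    shuffle_rng = np.random.default_rng(s_shuffle)
    eps_rng = np.random.default_rng(s_eps)
    history = []
    gen_steps = critic_steps = 0
    stop = False
    for epoch in range(config.gan_epochs):
        lr = config.lr_at(min(epoch, config.epochs - 1))
        g_opt.lr = d_opt.lr = lr
        order = shuffle_rng.permutation(len(names))
        for i0 in range(0, len(order), config.batch_size):
            idx = order[i0:i0 + config.batch_size]
            batch = {"y_prime": yp_all[idx], "b": b_all[idx],
                     "y_label": yl_all[idx], "x_label": xl_all[idx]}
            seed_gp = int(eps_rng.integers(2 ** 31))
            g_loss, d_loss, comps = wgan_objectives(
                henet, critic, batch, config.weights,
                projector=model.projector, seed=seed_gp)
            if critic_steps < config.critic_steps_per_gen * (gen_steps + 1):
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()
                critic_steps += 1
                role = "critic"
            else:
                g_opt.zero_grad()
                g_loss.backward()
                g_opt.step()
                gen_steps += 1
                role = "generator"
            history.append({"phase": 2, "epoch": epoch, "role": role,
                            "g_loss": float(g_loss.item()),
                            "d_loss": float(d_loss.item()), **comps})
            if config.max_gen_steps is not None \
                    and gen_steps >= config.max_gen_steps:
                stop = True
                break
        if stop:
            break
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, {"henet": henet, "critic": critic},
                        config, extra={"phase": 2})
    return henet, critic, history


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def reconstruct(x, stage1, stage2=None):
    """Full inference: sparse sinogram -> y' -> Sobel edges -> refined y_g.

    ``x`` may be a Sinogram or an (n_sparse, n_det) array; ``stage1`` a
    DualDomainModel or checkpoint path, ``stage2`` a HENet or checkpoint
    path (optional — without it ``y_g`` is None).  Returns ``(y', y_g)``.
    """
    if not isinstance(stage1, DualDomainModel):
        cfg, states, _ = load_checkpoint(stage1)
        stage1_model = build_stage1(cfg)
        stage1_model.sinet.load_state_dict(states["sinet"])
        stage1_model.ienet.load_state_dict(states["ienet"])
        stage1 = stage1_model
    xd = x.data if isinstance(x, Sinogram) else np.asarray(x)
    if isinstance(x, Sinogram) and \
            x.geometry.to_dict() != stage1.projector.geometry.to_dict():
        raise ValueError("sinogram geometry does not match checkpoints")
    y_prime = stage1.reconstruct(xd.astype(stage1.sinet._dtype))
    if stage2 is None:
        return y_prime, None
    if isinstance(stage2, HENet):
        henet = stage2
    else:
        cfg2, states2, _ = load_checkpoint(stage2)
        henet, _critic = build_stage2(cfg2)
        henet.load_state_dict(states2["henet"])
    b = sobel_edges(y_prime)
    y_g = henet.refine(y_prime, b)
    return y_prime, y_g


def evaluate(dataset: PhantomDataset, stage1, stage2=None,
             data_range: float = 1.0, csv_path=None, json_path=None):
    """Per-case metric table for sparse-FBP, y' and y_g against the reference."""
    if not dataset.test_cases:
        raise ValueError("empty test split")
    table = MetricsTable()
    for name in dataset.test_cases:
        case = dataset[name]
        ref = case["full_image"]
        table.add(name, "sparse_fbp",
                  evaluate_pair(case["sparse_fbp"], ref, data_range))
        y_prime, y_g = reconstruct(case["sparse_sino"], stage1, stage2)
        table.add(name, "y_prime", evaluate_pair(y_prime, ref, data_range))
        if y_g is not None:
            table.add(name, "y_g", evaluate_pair(y_g, ref, data_range))
    if csv_path:
        table.to_csv(csv_path)
    if json_path:
        table.to_json(json_path)
    return table
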