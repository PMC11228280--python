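"""Dual-stream adversarial autoencoder with an MLP-Mixer core.

The encoder runs two pipelines over each sample:

* an early-integration stream: the concatenated multi-omics vector (length D)
  is padded with ones into the smallest p-multiple square grid
  (H = W = ceil(sqrt(D)/p) * p), cut into p x p patches, linearly embedded to
  C channels and passed through token-mixing / channel-mixing MLP blocks with
  residual connections and pre-LayerNorm; mean-pooling over the patch axis
  yields a length-C code;
* a per-omics stream: one fully connected encoder per omics layer producing a
  hidden code per layer.

The codes are concatenated and reduced by an affine fusion layer to the
latent dimension (256 by default), with batch normalisation as the fusion
block's final op so the latent stays unbounded. A discriminator is trained
adversarially against draws from N(0, 1)^latent so the latent codes approach
the standard normal prior (in place of an explicit KL term); decoders
reconstruct each omics layer and the combined vector. The total loss is

    L = lambda1 * l1 + lambda2 * l2 + lambda3 * l3

where l1 and l3 are reconstruction errors (summed over features, averaged
over samples) of the combined and per-omics decoders and l2 is the
adversarial binary cross-entropy, with defaults lambda = (1, 1, 0.01), Adam
at learning rate 0.005, batch size 64, short training (see ModelConfig) and
early stopping on the reconstruction loss.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .autograd import Tensor, concatenate
from .io import MultiOmicsDataset, build_combined
from .nn import (
    Adam,
    BatchNorm1d,
    GELU,
    LayerNorm,
    Linear,
    Module,
    Sequential,
    Sigmoid,
    bce,
    gelu,
    mse,
)

WEIGHTS_FORMAT_VERSION = 1

log = logging.getLogger("omicsmix")


@dataclass
class ModelConfig:
    latent_dim: int = 256
    patch_size: int = 16
    embed_channels: int = 128
    n_mixer_layers: int = 2
    token_mlp_width: int | None = None  # None: 4x the patch count, set at build time
    channel_mlp_width: int = 256
    per_omics_hidden: int = 256
    disc_hidden: int = 64
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 0.01
    learning_rate: float = 0.005
    disc_learning_rate: float | None = None  # None: same rate as the autoencoder
    batch_size: int = 64
    # representation quality peaks within tens of epochs and then degrades as
    # the autoencoder starts memorising samples; the default follows the
    # reference regime of short training runs
    max_epochs: int = 12
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0
    use_mixer_stream: bool = True      # ablation switch: early-integration stream
    use_per_omics_stream: bool = True  # ablation switch: per-omics stream
    adversarial_label_flip: bool = False

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.patch_size < 1:
            raise ValueError("latent_dim and patch_size must be >= 1")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")
        if not (self.use_mixer_stream or self.use_per_omics_stream):
            raise ValueError("at least one encoder stream must be enabled")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TrainReport:
    l1: list[float] = field(default_factory=list)
    l2: list[float] = field(default_factory=list)
    l3: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    disc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    wall_time: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.total) + 1),
                "l1": self.l1,
                "l2": self.l2,
                "l3": self.l3,
                "total": self.total,
                "disc": self.disc,
            }
        )


# ---------------------------------------------------------------------------
# grid / patch geometry (plain NumPy; the encoder mirrors these with tensors)


def grid_size(D: int, p: int) -> int:
    """Side of the smallest p-multiple square holding D values."""
    if D < 1 or p < 1:
        raise ValueError("D and p must be >= 1")
    return int(math.ceil(math.sqrt(D) / p)) * p


@dataclass
class GridImage:
    H: int
    W: int
    cells: np.ndarray
    valid_length: int


@dataclass
class PatchTokens:
    tokens: np.ndarray  # N x p^2
    N: int


def reshape_to_grid(xa: np.ndarray, p: int) -> GridImage:
    """Row-major fill of the square grid; cells beyond D are padded with 1."""
    xa = np.asarray(xa, float).ravel()
    D = xa.size
    H = grid_size(D, p)
    flat = np.ones(H * H)
    flat[:D] = xa
    return GridImage(H=H, W=H, cells=flat.reshape(H, H), valid_length=D)


def inverse_grid(grid: GridImage) -> np.ndarray:
    return grid.cells.ravel()[: grid.valid_length].copy()


def patchify(grid: GridImage, p: int) -> PatchTokens:
    """Non-overlapping p x p tiles in row-major tile order, each flattened row-major."""
    H, W = grid.H, grid.W
    if H % p or W % p:
        raise ValueError("grid side must be a multiple of the patch size")
    tiles = grid.cells.reshape(H // p, p, W // p, p).transpose(0, 2, 1, 3)
    n = (H // p) * (W // p)
    return PatchTokens(tokens=tiles.reshape(n, p * p), N=n)


def embed_patches(tokens: PatchTokens, weights: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    out = tokens.tokens @ weights
    return out if bias is None else out + bias


# ---------------------------------------------------------------------------
# network modules


class MixerLayer(Module):
    """Pre-norm residual token mixing then channel mixing on (B, N, C) tokens."""

    def __init__(self, n_tokens: int, channels: int, token_width: int, channel_width: int,
                 rng: np.random.Generator):
        self.norm_tokens = LayerNorm(channels)
        self.token_fc1 = Linear(n_tokens, token_width, rng)
        self.token_fc2 = Linear(token_width, n_tokens, rng)
        self.norm_channels = LayerNorm(channels)
        self.channel_fc1 = Linear(channels, channel_width, rng)
        self.channel_fc2 = Linear(channel_width, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm_tokens(x).transpose(0, 2, 1)       # (B, C, N)
        y = self.token_fc2(gelu(self.token_fc1(y)))
        x = x + y.transpose(0, 2, 1)
        z = self.norm_channels(x)                        # (B, N, C)
        return x + self.channel_fc2(gelu(self.channel_fc1(z)))


class MixerEncoder(Module):
    """Pad -> grid -> patchify -> embed -> mixer layers -> mean over patches."""

    def __init__(self, D: int, cfg: ModelConfig, rng: np.random.Generator):
        self.D = D
        self.p = cfg.patch_size
        self.H = grid_size(D, self.p)
        self.n_tokens = (self.H // self.p) ** 2
        self.embed = Linear(self.p * self.p, cfg.embed_channels, rng)
        token_width = cfg.token_mlp_width if cfg.token_mlp_width else 4 * self.n_tokens
        self.layers = [
            MixerLayer(self.n_tokens, cfg.embed_channels, token_width,
                       cfg.channel_mlp_width, rng)
            for _ in range(cfg.n_mixer_layers)
        ]

    def tokens(self, xa: Tensor) -> Tensor:
        B = xa.shape[0]
        pad = self.H * self.H - self.D
        if pad:
            xa = concatenate([xa, Tensor(np.ones((B, pad)))], axis=1)
        hp = self.H // self.p
        tiles = xa.reshape(B, hp, self.p, hp, self.p).transpose(0, 1, 3, 2, 4)
        return tiles.reshape(B, self.n_tokens, self.p * self.p)

    def forward(self, xa: Tensor) -> Tensor:
        t = self.embed(self.tokens(xa))
        for layer in self.layers:
            t = layer(t)
        return t.mean(axis=1)  # pool over the patch (token) axis -> (B, C)


class Discriminator(Module):
    """Scores a latent code's resemblance to a draw from N(0,1)^latent."""

    def __init__(self, latent_dim: int, hidden: int, rng: np.random.Generator):
        self.net = Sequential(
            Linear(latent_dim, hidden, rng), GELU(), Linear(hidden, 1, rng), Sigmoid()
        )

    def forward(self, z: Tensor) -> Tensor:
        return self.net(z)


class MixerAutoencoder(Module):
    """Encoders, fusion and decoders (the discriminator is a separate module)."""

    def __init__(self, dims: list[int], cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.dims = list(dims)
        self.D = int(sum(dims))
        h = cfg.per_omics_hidden
        if cfg.use_per_omics_stream:
            self.omics_encoders = [Sequential(Linear(d, h, rng), GELU()) for d in dims]
        else:
            self.omics_encoders = []
        self.mixer = MixerEncoder(self.D, cfg, rng) if cfg.use_mixer_stream else None
        fusion_in = (h * len(dims) if cfg.use_per_omics_stream else 0) + (
            cfg.embed_channels if cfg.use_mixer_stream else 0
        )
        self.fusion = Linear(fusion_in, cfg.latent_dim, rng)
        self.fusion_bn = BatchNorm1d(cfg.latent_dim)
        self.omics_decoders = [
            Sequential(Linear(cfg.latent_dim, h, rng), GELU(), Linear(h, d, rng)) for d in dims
        ]
        self.combined_decoder = Sequential(
            Linear(cfg.latent_dim, h, rng), GELU(), Linear(h, self.D, rng)
        )

    # -- encoding ----------------------------------------------------------
    def _pre_norm(self, x_parts: list[Tensor], x_combined: Tensor) -> Tensor:
        """Fusion activation before the final batch normalisation.

        The fusion map itself is affine: the stream encoders already end in
        GELU, and a bounded activation at the latent would make the N(0,1)
        adversarial prior unreachable (saturated dimensions die and their
        latent variance collapses).
        """
        codes: list[Tensor] = []
        if self.cfg.use_per_omics_stream:
            codes.extend(enc(x) for enc, x in zip(self.omics_encoders, x_parts))
        if self.mixer is not None:
            codes.append(self.mixer(x_combined))
        return self.fusion(concatenate(codes, axis=1) if len(codes) > 1 else codes[0])

    def encode(self, x_parts: list[Tensor], x_combined: Tensor) -> Tensor:
        # batch normalisation is the fusion layer's last op, so the latent is
        # unbounded and can actually match the N(0,1) adversarial prior
        return self.fusion_bn(self._pre_norm(x_parts, x_combined))

    def finalize_batch_stats(self, x_parts: list[Tensor], x_combined: Tensor) -> None:
        """Replace the EMA batch-norm statistics with exact full-data statistics.

        After this, inference-mode latent codes have per-dimension mean beta
        and variance gamma^2 by construction, eliminating the train/inference
        statistics mismatch of the EMA estimate.
        """
        act = self._pre_norm(x_parts, x_combined).data
        self.fusion_bn.running_mean = act.mean(axis=0)
        self.fusion_bn.running_var = act.var(axis=0)

    # -- losses --------------------------------------------------------------
    def loss_terms(
        self,
        x_parts: list[Tensor],
        x_combined: Tensor,
        discriminator: Discriminator,
        z: Tensor | None = None,
    ) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
        """Returns (l1, l2, l3, L, Z); ``z`` may be a precomputed encoder output."""
        cfg = self.cfg
        if z is None:
            z = self.encode(x_parts, x_combined)
        # reconstruction errors are summed over features and averaged over
        # samples: on this scale the published weights (1, 1, 0.01) are
        # coherent -- reconstruction dominates, 0.01 tames the extra
        # per-omics terms, and the O(1) adversarial BCE is a gentle nudge
        l1 = mse(self.combined_decoder(z), x_combined) * float(x_combined.shape[1])
        adv_target = 0.0 if cfg.adversarial_label_flip else 1.0
        l2 = bce(discriminator(z), adv_target)
        l3 = Tensor(0.0)
        for dec, x in zip(self.omics_decoders, x_parts):
            l3 = l3 + mse(dec(z), x) * float(x.shape[1])
        total = cfg.lambda1 * l1 + cfg.lambda2 * l2 + cfg.lambda3 * l3
        return l1, l2, l3, total, z


@dataclass
class NetworkWeights:
    """Learned parameters of the network and discriminator plus the geometry."""

    config: ModelConfig
    dims: list[int]
    network_state: dict[str, np.ndarray]
    discriminator_state: dict[str, np.ndarray]
    running_mean: np.ndarray
    running_var: np.ndarray
    version: int = WEIGHTS_FORMAT_VERSION

    def build(self) -> tuple[MixerAutoencoder, Discriminator]:
        rng = np.random.default_rng(0)
        net = MixerAutoencoder(self.dims, self.config, rng)
        disc = Discriminator(self.config.latent_dim, self.config.disc_hidden, rng)
        net.load_state_dict(self.network_state)
        disc.load_state_dict(self.discriminator_state)
        net.fusion_bn.running_mean = self.running_mean.copy()
        net.fusion_bn.running_var = self.running_var.copy()
        return net, disc

    def save(self, path) -> None:
        arrays = {"__version__": np.array([self.version])}
        arrays.update({f"net_{k}": v for k, v in self.network_state.items()})
        arrays.update({f"disc_{k}": v for k, v in self.discriminator_state.items()})
        arrays["running_mean"] = self.running_mean
        arrays["running_var"] = self.running_var
        arrays["dims"] = np.asarray(self.dims)
        np.savez(path, config=np.frombuffer(yaml.safe_dump(asdict(self.config)).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "NetworkWeights":
        with np.load(path) as data:
            cfg = ModelConfig(**yaml.safe_load(bytes(data["config"]).decode()))
            net_state = {k[4:]: data[k] for k in data.files if k.startswith("net_")}
            disc_state = {k[5:]: data[k] for k in data.files if k.startswith("disc_")}
            return cls(
                config=cfg,
                dims=[int(d) for d in data["dims"]],
                network_state=net_state,
                discriminator_state=disc_state,
                running_mean=data["running_mean"],
                running_var=data["running_var"],
                version=int(data["__version__"][0]),
            )


# ---------------------------------------------------------------------------
# training


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(dataset: MultiOmicsDataset, cfg: ModelConfig) -> tuple[NetworkWeights, TrainReport]:
    """Alternating adversarial training; fully deterministic given cfg.seed."""
    t0 = time.perf_counter()
    combined, _ = build_combined(dataset)
    parts = [m.values for m in dataset.omics]
    dims = [m.n_features for m in dataset.omics]
    n = combined.shape[0]

    rng = np.random.default_rng(cfg.seed)
    net = MixerAutoencoder(dims, cfg, rng)
    disc = Discriminator(cfg.latent_dim, cfg.disc_hidden, rng)
    opt_ae = Adam(net.parameters(), lr=cfg.learning_rate)
    disc_lr = cfg.disc_learning_rate if cfg.disc_learning_rate is not None else cfg.learning_rate
    opt_d = Adam(disc.parameters(), lr=disc_lr)

    prior_label = 0.0 if cfg.adversarial_label_flip else 1.0
    report = TrainReport()
    best = math.inf
    wait = 0
    for epoch in range(1, cfg.max_epochs + 1):
        sums = np.zeros(5)
        n_batches = 0
        for idx in _batches(n, cfg.batch_size, rng):
            xb_parts = [Tensor(p[idx]) for p in parts]
            xb_combined = Tensor(combined[idx])

            # discriminator step: prior draws vs detached encoder outputs
            net.train()
            z = net.encode(xb_parts, xb_combined)
            prior = Tensor(rng.standard_normal((len(idx), cfg.latent_dim)))
            d_loss = 0.5 * (
                bce(disc(prior), prior_label) + bce(disc(z.detach()), 1.0 - prior_label)
            )
            disc.zero_grad()
            d_loss.backward()
            opt_d.step()

            # autoencoder + encoder step on the full objective (encoder
            # forward reused; l2 sees the just-updated discriminator)
            l1, l2, l3, total, _ = net.loss_terms(xb_parts, xb_combined, disc, z=z)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(l1={float(l1.data):.4g}, l2={float(l2.data):.4g}, l3={float(l3.data):.4g})"
                )
            net.zero_grad()
            disc.zero_grad()  # l2 backprops into the discriminator; discard those grads
            total.backward()
            opt_ae.step()

            sums += [float(l1.data), float(l2.data), float(l3.data), float(total.data),
                     float(d_loss.data)]
            n_batches += 1

        means = sums / n_batches
        log.info(
            "epoch %d: l1=%.4f l2=%.4f l3=%.4f total=%.4f disc=%.4f",
            epoch, *means,
        )
        report.l1.append(means[0])
        report.l2.append(means[1])
        report.l3.append(means[2])
        report.total.append(means[3])
        report.disc.append(means[4])
        report.stopped_epoch = epoch

        # early stopping monitors the reconstruction objective only: the
        # adversarial term hovers around ln 2 at equilibrium and would mask
        # reconstruction progress
        monitored = cfg.lambda1 * means[0] + cfg.lambda3 * means[2]
        if best - monitored > cfg.min_delta:
            best = monitored
            wait = 0
        else:
            wait += 1
            if wait > cfg.patience:
                break

    net.eval()
    net.finalize_batch_stats([Tensor(p) for p in parts], Tensor(combined))
    report.wall_time = time.perf_counter() - t0
    weights = NetworkWeights(
        config=cfg,
        dims=dims,
        network_state=net.state_dict(),
        discriminator_state=disc.state_dict(),
        running_mean=net.fusion_bn.running_mean.copy(),
        running_var=net.fusion_bn.running_var.copy(),
    )
    return weights, report


def encode_dataset(weights: NetworkWeights, dataset: MultiOmicsDataset) -> np.ndarray:
    """Latent matrix (n_samples x latent_dim) in inference mode (running stats)."""
    net, _ = weights.build()
    net.eval()
    parts = [Tensor(m.values) for m in dataset.omics]
    combined, _ = build_combined(dataset)
    z = net.encode(parts, Tensor(combined))
    return np.asarray(z.data)
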