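"""Network architectures for rim+/rim- patch classification.

Two architectures are provided, both VGG-style stacks of three blocks of
two 3x3x3 'same' convolutions followed by 2x2x2 max-pooling, with batch
normalisation and tanh activations:

* a bimodal network with two parallel branches (main and secondary
  modality).  The secondary branch's first-block output is channel-
  concatenated onto the main branch's first-block output before the main
  branch's second block (early fusion of low-level features); the final
  feature blocks of both branches are flattened, concatenated and fed to a
  cascade of fully connected layers ending in a 2-way softmax (late
  fusion of high-level features).
* a unimodal baseline: a single branch connected to the same head.

With the default 28-voxel patches the per-branch spatial trace is
28 -> 14 -> 7 -> 3.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .patches import Patch


@dataclass
class ArchConfig:
    modalities: tuple[str, ...] = ("phase", "flair")   # (main, secondary)
    blocks_per_branch: int = 3
    convs_per_block: int = 2
    filters: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    fc_widths: tuple[int, ...] = (256, 64)
    activation: str = "tanh"
    batch_norm: bool = True
    n_classes: int = 2
    early_fusion: bool = True

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        self.filters = tuple(self.filters)
        self.fc_widths = tuple(self.fc_widths)
        if len(self.modalities) not in (1, 2):
            raise ValueError("1 (unimodal) or 2 (bimodal) modalities required")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError("modalities must be distinct")
        if self.blocks_per_branch != 3 or self.convs_per_block != 2:
            raise ValueError("architecture is fixed at 3 blocks of 2 convs")
        if len(self.filters) != self.blocks_per_branch:
            raise ValueError("one filter count per block required")
        if self.kernel_size != 3 or self.pool_size != 2:
            raise ValueError("engine supports kernel 3 and pool 2 only")
        if self.activation != "tanh":
            raise ValueError("tanh is the only supported activation")
        if self.n_classes != 2:
            raise ValueError("binary rim+/rim- classification only")
        if self.early_fusion and len(self.modalities) != 2:
            raise ValueError("early fusion requires two modalities")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        return cls(**d)

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _block(c_in: int, c_out: int, rng: np.random.Generator,
           batch_norm: bool, input_block: bool = False) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for i in range(2):
        layers.append(nn.Conv3dSame(c_in if i == 0 else c_out, c_out, rng,
                                    input_grad=not (input_block and i == 0)))
        if batch_norm:
            layers.append(nn.BatchNorm3d(c_out))
        layers.append(nn.Tanh())
    layers.append(nn.MaxPool3d())
    return nn.Sequential(layers)


def _head(n_in: int, fc_widths: tuple[int, ...], n_classes: int,
          rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    prev = n_in
    for w in fc_widths:
        layers.append(nn.Dense(prev, w, rng))
        layers.append(nn.Tanh())
        prev = w
    layers.append(nn.Dense(prev, n_classes, rng))
    return nn.Sequential(layers)


def spatial_trace(patch_size: int, n_blocks: int = 3) -> list[int]:
    """Spatial edge length after each pooling stage (floor division)."""
    out = [patch_size]
    for _ in range(n_blocks):
        out.append(out[-1] // 2)
    return out


class _Network:
    """Common surface: forward to logits, backward, (de)serialisation."""

    def __init__(self, config: ArchConfig, seed: int):
        self.config = config
        self.seed = seed

    # -- implemented by subclasses -------------------------------------
    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def parameters(self) -> list[nn.Parameter]:
        raise NotImplementedError

    # -- shared ---------------------------------------------------------
    @property
    def n_modalities(self) -> int:
        return len(self.config.modalities)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def predict_proba(self, xs: list[np.ndarray],
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities (n, 2) in eval mode (running BN statistics)."""
        n = xs[0].shape[0]
        out = np.empty((n, self.config.n_classes))
        for i in range(0, n, batch_size):
            logits = self.forward([x[i:i + batch_size] for x in xs],
                                  training=False)
            out[i:i + batch_size] = nn.softmax(logits.astype(np.float64))
        return out

    def save_weights(self, path: str) -> None:
        arrays = {f"p{i:04d}": p.value
                  for i, p in enumerate(self.parameters())}
        bn_state = {}
        for i, l in enumerate(self._all_layers()):
            if isinstance(l, nn.BatchNorm3d):
                bn_state[f"bn{i:04d}_mean"] = l.running_mean
                bn_state[f"bn{i:04d}_var"] = l.running_var
        np.savez(path, _fingerprint=self.config.fingerprint(),
                 _config=json.dumps(self.config.to_dict()),
                 **arrays, **bn_state)

    def load_weights(self, path: str) -> None:
        with np.load(path, allow_pickle=False) as z:
            fp = str(z["_fingerprint"])
            if fp != self.config.fingerprint():
                raise ValueError(
                    f"checkpoint fingerprint {fp} does not match this "
                    f"architecture ({self.config.fingerprint()})")
            for i, p in enumerate(self.parameters()):
                p.value[...] = z[f"p{i:04d}"]
            for i, l in enumerate(self._all_layers()):
                if isinstance(l, nn.BatchNorm3d):
                    l.running_mean[...] = z[f"bn{i:04d}_mean"]
                    l.running_var[...] = z[f"bn{i:04d}_var"]

    def _all_layers(self) -> list[nn.Layer]:
        out = []
        for seq in self._sequences():
            out.extend(seq.layers)
        return out

    def _sequences(self) -> list[nn.Sequential]:
        raise NotImplementedError


class BimodalNetwork(_Network):
    """Two parallel branches with early (block-1) and late (head) fusion."""

    def __init__(self, config: ArchConfig, seed: int = 0):
        super().__init__(config, seed)
        if len(config.modalities) != 2:
            raise ValueError("bimodal network requires two modalities")
        rng = np.random.default_rng(seed)
        f1, f2, f3 = config.filters
        bn = config.batch_norm
        self.main_b1 = _block(1, f1, rng, bn, input_block=True)
        self.sec_b1 = _block(1, f1, rng, bn, input_block=True)
        main_c2 = f1 * 2 if config.early_fusion else f1
        self.main_rest = nn.Sequential(
            _block(main_c2, f2, rng, bn).layers + _block(f2, f3, rng, bn).layers)
        self.sec_rest = nn.Sequential(
            _block(f1, f2, rng, bn).layers + _block(f2, f3, rng, bn).layers)
        self._f1, self._f3 = f1, f3
        self._head: nn.Sequential | None = None
        self._head_rng = rng

    def _ensure_head(self, feat_dim: int) -> None:
        if self._head is None:
            self._head = _head(feat_dim, self.config.fc_widths,
                               self.config.n_classes, self._head_rng)

    def parameters(self) -> list[nn.Parameter]:
        seqs = self._sequences()
        return [p for s in seqs for p in s.parameters()]

    def _sequences(self) -> list[nn.Sequential]:
        seqs = [self.main_b1, self.sec_b1, self.main_rest, self.sec_rest]
        if self._head is not None:
            seqs.append(self._head)
        return seqs

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        x_main, x_sec = xs
        m1 = self.main_b1.forward(x_main, training)
        s1 = self.sec_b1.forward(x_sec, training)
        fused = (np.concatenate([m1, s1], axis=1)
                 if self.config.early_fusion else m1)
        m3 = self.main_rest.forward(fused, training)
        s3 = self.sec_rest.forward(s1, training)
        self._m3_shape, self._s3_shape = m3.shape, s3.shape
        feats = np.concatenate([m3.reshape(m3.shape[0], -1),
                                s3.reshape(s3.shape[0], -1)], axis=1)
        self._ensure_head(feats.shape[1])
        return self._head.forward(feats, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self._head.backward(dlogits)
        n_main = int(np.prod(self._m3_shape[1:]))
        gm3 = g[:, :n_main].reshape(self._m3_shape)
        gs3 = g[:, n_main:].reshape(self._s3_shape)
        gfused = self.main_rest.backward(gm3)
        gs1 = self.sec_rest.backward(gs3)
        if self.config.early_fusion:
            gm1 = gfused[:, :self._f1]
            gs1 = gs1 + gfused[:, self._f1:]
        else:
            gm1 = gfused
        self.main_b1.backward(np.ascontiguousarray(gm1))
        self.sec_b1.backward(np.ascontiguousarray(gs1))


class UnimodalNetwork(_Network):
    """Single branch directly connected to the fully connected cascade."""

    def __init__(self, config: ArchConfig, seed: int = 0):
        super().__init__(config, seed)
        if len(config.modalities) != 1:
            raise ValueError("unimodal network requires one modality")
        rng = np.random.default_rng(seed)
        f1, f2, f3 = config.filters
        bn = config.batch_norm
        self.branch = nn.Sequential(
            _block(1, f1, rng, bn, input_block=True).layers + _block(f1, f2, rng, bn).layers
            + _block(f2, f3, rng, bn).layers)
        self._head: nn.Sequential | None = None
        self._head_rng = rng

    def parameters(self) -> list[nn.Parameter]:
        return [p for s in self._sequences() for p in s.parameters()]

    def _sequences(self) -> list[nn.Sequential]:
        return ([self.branch, self._head] if self._head is not None
                else [self.branch])

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        out = self.branch.forward(xs[0], training)
        self._out_shape = out.shape
        feats = out.reshape(out.shape[0], -1)
        if self._head is None:
            self._head = _head(feats.shape[1], self.config.fc_widths,
                               self.config.n_classes, self._head_rng)
        return self._head.forward(feats, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self._head.backward(dlogits)
        self.branch.backward(g.reshape(self._out_shape))


def build_rimnet(arch: ArchConfig, seed: int = 0) -> BimodalNetwork:
    """Build the bimodal early+late fusion network."""
    return BimodalNetwork(arch, seed)


def build_unimodal(arch: ArchConfig, seed: int = 0) -> UnimodalNetwork:
    """Build the single-branch baseline."""
    return UnimodalNetwork(arch, seed)


def build_network(arch: ArchConfig, seed: int = 0) -> _Network:
    return (build_rimnet(arch, seed) if len(arch.modalities) == 2
            else build_unimodal(arch, seed))


def stack_patches(patches: list[Patch], modalities: tuple[str, ...]
                  ) -> list[np.ndarray]:
    """Patch list -> per-modality arrays (n, 1, p, p, p), config order."""
    return [np.stack([p.data[m] for p in patches])[:, None].astype(np.float32)
            for m in modalities]
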