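"""Multi-scale multi-scan (MSMS) volume serialization.

A 3-D feature grid is uniformly partitioned into ``N`` segments per axis
(``N`` even, default 4), giving ``N^3`` basic elements.  Picking one parity
class of segment indices per axis (paper-style odd = {1,3,...} or even =
{2,4,...}, 1-based) yields 8 sub-volumes (SVs) that partition the elements.
Each SV is flattened into a 1-D sequence by its own fixed traversal order of
its 8 element octants — the orders differ in axis priority and direction, so
the 8 sequences jointly cover the volume from complementary directions at
half the spatial sample rate per axis.  ``multi_merge`` is the exact inverse.

The dual-branch MSMS module runs a selective SSM over the 8 sub-volume
sequences (upper branch, coarse scale) and over the full-resolution raster
(lower branch), then sums the reconstructions.  The MSMS block wraps the
module with layer norms, residual paths and a convolutional feed-forward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .ssm_core import SelectiveParams, selective_scan

__all__ = [
    "SCAN_ORDERS",
    "SubVolumeSpec",
    "ScanPlan",
    "build_scan_plan",
    "multi_scan",
    "multi_merge",
    "msms_module",
    "SelectiveSSMLayer",
    "MSMSModule",
    "MSMSBlock",
]

# Per sub-volume: axis parity offsets (0 = paper-odd class {x1,x3,...},
# 1 = paper-even class {x2,x4,...}) and the octant traversal order.
SCAN_ORDERS: list[tuple[tuple[int, int, int], tuple[int, ...]]] = [
    ((0, 0, 0), (1, 2, 3, 4, 5, 6, 7, 8)),
    ((1, 0, 0), (8, 7, 6, 5, 4, 3, 2, 1)),
    ((0, 1, 0), (1, 3, 2, 4, 5, 7, 6, 8)),
    ((1, 1, 0), (8, 6, 7, 5, 4, 2, 3, 1)),
    ((0, 0, 1), (1, 5, 2, 6, 3, 7, 4, 8)),
    ((1, 0, 1), (8, 4, 7, 3, 6, 2, 5, 1)),
    ((0, 1, 1), (1, 2, 4, 3, 5, 6, 8, 7)),
    ((1, 1, 1), (7, 8, 6, 5, 3, 4, 2, 1)),
]


@dataclass(frozen=True)
class SubVolumeSpec:
    parity: tuple[int, int, int]      # segment-index offset per axis (0 or 1)
    order: tuple[int, ...]            # traversal order of the 8 octants
    reverse: bool                     # descending raster sense inside octants


@dataclass
class ScanPlan:
    """Partition of a grid into basic elements and 8 scan sequences."""

    n_segments: int
    spatial_shape: tuple[int, int, int]
    subvolumes: list[SubVolumeSpec]
    _perms: np.ndarray | None = field(default=None, repr=False)
    _inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_elements(self) -> int:
        return self.n_segments**3

    @property
    def elements_per_subvolume(self) -> int:
        return self.n_elements // 8

    @property
    def element_shape(self) -> tuple[int, int, int]:
        return tuple(s // self.n_segments for s in self.spatial_shape)

    def element_slices(self, i: int, j: int, k: int) -> tuple[slice, slice, slice]:
        """Voxel block of basic element ``(i, j, k)`` (1-based triples)."""
        N = self.n_segments
        if not all(1 <= t <= N for t in (i, j, k)):
            raise ValueError(f"element indices must be in 1..{N}")
        ex, ey, ez = self.element_shape
        return (
            slice((i - 1) * ex, i * ex),
            slice((j - 1) * ey, j * ey),
            slice((k - 1) * ez, k * ez),
        )

    # -- flat voxel permutations -------------------------------------------

    def permutations(self) -> tuple[np.ndarray, np.ndarray]:
        """(8, L) visit-order indices into the C-flattened spatial grid,
        and the inverse permutation of their concatenation."""
        if self._perms is None:
            perms = np.stack(
                [self._sv_permutation(sv) for sv in self.subvolumes]
            )
            flat = perms.reshape(-1)
            inv = np.empty_like(flat)
            inv[flat] = np.arange(flat.size)
            self._perms, self._inv = perms, inv
        return self._perms, self._inv

    def _sv_permutation(self, sv: SubVolumeSpec) -> np.ndarray:
        N = self.n_segments
        X, Y, Z = self.spatial_shape
        ex, ey, ez = self.element_shape
        m = N // 2  # elements per axis in one SV
        half = m // 2  # elements per axis in one octant
        # element coordinates (0-based segment indices) per axis for this SV
        ax = [sv.parity[a] + 2 * np.arange(m) for a in range(3)]
        # x-fastest raster over one element block, as C-order flat offsets
        ox, oy, oz = np.meshgrid(
            np.arange(ex), np.arange(ey), np.arange(ez), indexing="ij"
        )
        block = (ox * Y * Z + oy * Z + oz).transpose(2, 1, 0).reshape(-1)
        if sv.reverse:
            block = block[::-1]
        chunks: list[np.ndarray] = []
        for onum in sv.order:
            o = onum - 1
            oct_ix, oct_iy, oct_iz = o % 2, (o // 2) % 2, o // 4
            if m == 1:
                if o > 0:
                    continue  # single element: orders degenerate
                coords = [(0, 0, 0)]
            else:
                rng = np.arange(half)
                tx, ty, tz = np.meshgrid(rng, rng, rng, indexing="ij")
                tri = np.stack(
                    [tx.transpose(2, 1, 0).reshape(-1),
                     ty.transpose(2, 1, 0).reshape(-1),
                     tz.transpose(2, 1, 0).reshape(-1)], axis=1
                )
                if sv.reverse:
                    tri = tri[::-1]
                coords = [
                    (oct_ix * half + t[0], oct_iy * half + t[1], oct_iz * half + t[2])
                    for t in tri
                ]
            for cx, cy, cz in coords:
                bx, by, bz = ax[0][cx] * ex, ax[1][cy] * ey, ax[2][cz] * ez
                chunks.append(block + (bx * Y * Z + by * Z + bz))
        return np.concatenate(chunks)

    # -- sidecar serialization ---------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_segments": self.n_segments,
                "spatial_shape": list(self.spatial_shape),
                "subvolumes": [
                    {"parity": list(sv.parity), "order": list(sv.order),
                     "reverse": sv.reverse}
                    for sv in self.subvolumes
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScanPlan":
        d = json.loads(text)
        return cls(
            d["n_segments"],
            tuple(d["spatial_shape"]),
            [
                SubVolumeSpec(tuple(sv["parity"]), tuple(sv["order"]), sv["reverse"])
                for sv in d["subvolumes"]
            ],
        )


def build_scan_plan(
    n_segments: int, spatial_shape: tuple[int, int, int]
) -> ScanPlan:
    """Construct the 8-sub-volume scan plan for a grid.

    ``n_segments`` must be even (parity pairing needs two classes per axis)
    and, above 4, a multiple of 4 so the octant traversal is defined; every
    spatial extent must be divisible by ``n_segments``.
    """
    N = int(n_segments)
    if N < 2 or N % 2:
        raise ValueError(f"n_segments must be a positive even integer, got {N}")
    if N > 2 and (N // 2) % 2:
        raise ValueError("n_segments above 2 must be a multiple of 4")
    shape = tuple(int(s) for s in spatial_shape)
    if any(s < N or s % N for s in shape):
        raise ValueError(
            f"spatial extents {shape} must be >= and divisible by n_segments={N}"
        )
    svs = [
        SubVolumeSpec(parity, order, reverse=bool(parity[0]))
        for parity, order in SCAN_ORDERS
    ]
    return ScanPlan(N, shape, svs)


def multi_scan(g: np.ndarray, plan: ScanPlan) -> list[np.ndarray]:
    """Flatten a feature grid into the 8 sub-volume sequences.

    ``g`` has shape ``(C, X, Y, Z)``; each returned sequence has shape
    ``(C, X*Y*Z // 8)`` and the 8 jointly cover every voxel exactly once.
    """
    g = np.asarray(g)
    if g.ndim != 4:
        raise ValueError("feature grid must be (C, X, Y, Z)")
    if tuple(g.shape[1:]) != plan.spatial_shape:
        raise ValueError(
            f"grid spatial shape {g.shape[1:]} != plan shape {plan.spatial_shape}"
        )
    perms, _ = plan.permutations()
    flat = g.reshape(g.shape[0], -1)
    return [flat[:, p] for p in perms]


def multi_merge(seqs: list[np.ndarray], plan: ScanPlan) -> np.ndarray:
    """Exact inverse of :func:`multi_scan`."""
    if len(seqs) != 8:
        raise ValueError("expected 8 sequences")
    L = int(np.prod(plan.spatial_shape)) // 8
    if any(s.shape[-1] != L for s in seqs):
        raise ValueError(f"sequence lengths inconsistent with plan (expected {L})")
    perms, _ = plan.permutations()
    C = seqs[0].shape[0]
    out = np.empty((C, int(np.prod(plan.spatial_shape))), dtype=seqs[0].dtype)
    for p, s in zip(perms, seqs):
        out[:, p] = s
    return out.reshape((C,) + plan.spatial_shape)


def msms_module(
    g: np.ndarray,
    plan: ScanPlan,
    upper: SelectiveParams,
    lower: SelectiveParams,
) -> np.ndarray:
    """Functional dual-branch MSMS module (numpy, inference only).

    Upper branch: multi-scan -> selective scan per sequence -> multi-merge.
    Lower branch: selective scan over the full-resolution x-fastest raster.
    Fusion: elementwise sum.  Token dimension is the channel axis.
    """
    g = np.asarray(g, dtype=float)
    seqs = multi_scan(g, plan)
    X = np.stack([s.T for s in seqs])            # (8, L, C)
    Y = selective_scan(upper, X)
    up = multi_merge([y.T for y in Y], plan)
    raster = g.transpose(3, 2, 1, 0).reshape(-1, g.shape[0])  # x-fastest tokens
    low_seq = selective_scan(lower, raster)
    low = low_seq.reshape(g.shape[3], g.shape[2], g.shape[1], g.shape[0]).transpose(
        3, 2, 1, 0
    )
    return up + low


# ---------------------------------------------------------------------------
# Trainable layers


class SelectiveSSMLayer(Module):
    """Selective scan with learned projections (token dimension = channels).

    The output projection ``W_C`` starts at zero so a freshly initialized
    layer is a no-op inside residual blocks; every other projection follows
    the standard diagonal-SSM initialization of :meth:`SelectiveParams.init`.
    """

    def __init__(self, d: int, n_state: int, rng: np.random.Generator):
        sp = SelectiveParams.init(d, n_state, rng, c_scale=0.0)
        self.A_log = Parameter(np.log(-sp.A), decay=False)
        self.W_B = Parameter(sp.W_B)
        self.b_B = Parameter(sp.b_B, decay=False)
        self.W_C = Parameter(sp.W_C)
        self.b_C = Parameter(sp.b_C, decay=False)
        self.W_dt = Parameter(sp.W_dt)
        self.b_dt = Parameter(sp.b_dt, decay=False)

    def to_selective_params(self) -> SelectiveParams:
        return SelectiveParams(
            -np.exp(self.A_log.data), self.W_B.data, self.b_B.data,
            self.W_C.data, self.b_C.data, self.W_dt.data, self.b_dt.data,
        )

    def forward(self, X: Tensor) -> Tensor:
        """``X``: (S, L, d) tokens -> (S, L, d)."""
        S, L, d = X.shape
        n = self.A_log.shape[1]
        A = -self.A_log.exp()                                    # (d, N)
        B = ad.einsum("sld,nd->sln", X, self.W_B) + self.b_B
        C = ad.einsum("sld,nd->sln", X, self.W_C) + self.b_C
        dt = (ad.einsum("sld,ed->sle", X, self.W_dt) + self.b_dt).softplus()
        dt4 = dt.reshape((S, L, d, 1))
        half = dt4 * A.reshape((1, 1, d, n)) * 0.5
        den = 1.0 - half
        a_bar = (1.0 + half) / den
        b_bar = dt4 * B.reshape((S, L, 1, n)) / den              # (S, L, d, N)
        b_u = b_bar * X.reshape((S, L, d, 1))
        h = ad.linear_scan(
            a_bar.transpose((1, 0, 2, 3)), b_u.transpose((1, 0, 2, 3))
        )                                                        # (L, S, d, N)
        return ad.einsum("lsdn,sln->sld", h, C)


class MSMSModule(Module):
    """Dual-branch (multi-scale + full-resolution) selective scan module."""

    def __init__(self, channels: int, n_state: int, n_segments: int,
                 rng: np.random.Generator):
        self.n_segments = n_segments
        self.upper = SelectiveSSMLayer(channels, n_state, rng)
        self.lower = SelectiveSSMLayer(channels, n_state, rng)
        self._plans: dict[tuple[int, int, int], ScanPlan] = {}

    def _plan_for(self, shape: tuple[int, int, int]) -> ScanPlan:
        if shape not in self._plans:
            self._plans[shape] = build_scan_plan(self.n_segments, shape)
        return self._plans[shape]

    def forward(self, g: Tensor) -> Tensor:
        C, X, Y, Z = g.shape
        N = self.n_segments
        padded_shape = tuple(-(-s // N) * N for s in (X, Y, Z))
        gp = g
        if padded_shape != (X, Y, Z):
            gp = ad.pad_spatial(
                g, [(0, 0)] + [(0, ps - s) for ps, s in zip(padded_shape, (X, Y, Z))]
            )
        plan = self._plan_for(padded_shape)
        perms, inv = plan.permutations()
        V = int(np.prod(padded_shape))
        flat = gp.reshape((C, V))
        seq = ad.permute_last(flat, perms.reshape(-1), inv)      # scan order
        tokens = seq.reshape((C, 8, V // 8)).transpose((1, 2, 0))
        out = self.upper.forward(tokens)                         # (8, L, C)
        merged = ad.permute_last(
            out.transpose((2, 0, 1)).reshape((C, V)), inv, perms.reshape(-1)
        ).reshape((C,) + padded_shape)
        if padded_shape != (X, Y, Z):
            merged = ad.crop(
                merged, [slice(None), slice(0, X), slice(0, Y), slice(0, Z)]
            )
        # lower branch: x-fastest raster at native resolution
        raster = g.transpose((3, 2, 1, 0)).reshape((1, X * Y * Z, C))
        low = self.lower.forward(raster)
        low_grid = low.reshape((Z, Y, X, C)).transpose((3, 2, 1, 0))
        return merged + low_grid


class LayerNormChannels(Module):
    """Layer normalization over the channel axis of a (C, X, Y, Z) grid."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.eps = eps
        self.gamma = Parameter(np.ones((channels, 1, 1, 1)), decay=False)
        self.beta = Parameter(np.zeros((channels, 1, 1, 1)), decay=False)

    def forward(self, g: Tensor) -> Tensor:
        mu = g.mean(axis=0, keepdims=True)
        xc = g - mu
        var = (xc * xc).mean(axis=0, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class ConvFFN(Module):
    """Two pointwise 3-D convolutions with expansion and GELU in between.

    The second projection starts at zero, making a fresh block residual-safe.
    """

    def __init__(self, channels: int, expansion: int, rng: np.random.Generator):
        hidden = channels * expansion
        self.w1 = Parameter(rng.normal(0.0, (2.0 / channels) ** 0.5, (hidden, channels)))
        self.b1 = Parameter(np.zeros((hidden, 1, 1, 1)), decay=False)
        self.w2 = Parameter(np.zeros((channels, hidden)))
        self.b2 = Parameter(np.zeros((channels, 1, 1, 1)), decay=False)

    def forward(self, g: Tensor) -> Tensor:
        h = (ad.einsum("hc,cxyz->hxyz", self.w1, g) + self.b1).gelu()
        return ad.einsum("ch,hxyz->cxyz", self.w2, h) + self.b2


class MSMSBlock(Module):
    """LayerNorm -> MSMS module -> residual -> LayerNorm -> conv FFN -> residual."""

    def __init__(self, channels: int, n_state: int, expansion: int,
                 rng: np.random.Generator, n_segments: int = 4,
                 d_conv: int = 4):
        # d_conv is part of the published configuration; the internal wiring
        # it would parameterize is unconstrained, so it is recorded only.
        self.d_conv = d_conv
        self.norm1 = LayerNormChannels(channels)
        self.module = MSMSModule(channels, n_state, n_segments, rng)
        self.norm2 = LayerNormChannels(channels)
        self.ffn = ConvFFN(channels, expansion, rng)

    def forward(self, g: Tensor) -> Tensor:
        h = g + self.module.forward(self.norm1.forward(g))
        return h + self.ffn.forward(self.norm2.forward(h))

    def __call__(self, g: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.asarray(g, dtype=float))).data
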