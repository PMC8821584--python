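"""Encoder-decoder segmentation models.

Two encoder families share one U-Net-shaped graph:

* ``tiny`` - four plain conv-BN-ReLU downsampling stages (~0.1 M
  parameters), the desk-scale profile used throughout the test suite.
* ``b0`` .. ``b7`` - EfficientNet-style encoders built from
  inverted-bottleneck MBConv blocks (expansion 1 with ReLU, expansion 6
  with ReLU6; the residual skip is omitted in the first block of each
  stage), scaled by the usual compound width/depth coefficients, with
  five downsampling stages and a five-stage decoder.

The decoder upsamples (nearest x2), concatenates the matching encoder
feature map and applies a conv-BN-ReLU fusion; the head is a 1x1
projection to 3 class logits.  ``predict`` applies softmax downstream.
"""

from __future__ import annotations

import math

import numpy as np

from .layers import (Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, Layer, ReLU,
                     ReLU6, Upsample2x)

# EfficientNet-B0 backbone: (expansion, channels, repeats, stride, kernel)
_EFF_STAGES = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]
# compound scaling (width, depth) per variant
_EFF_SCALING = {
    "b0": (1.0, 1.0), "b1": (1.0, 1.1), "b2": (1.1, 1.2), "b3": (1.2, 1.4),
    "b4": (1.4, 1.8), "b5": (1.6, 2.2), "b6": (1.8, 2.6), "b7": (2.0, 3.1),
}


def _round_filters(c: int, width: float) -> int:
    return max(8, int(round(c * width / 8.0)) * 8)


def _round_repeats(r: int, depth: float) -> int:
    return int(math.ceil(r * depth))


class _Seq:
    """A named chain of layers with symmetric forward/backward."""

    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def sublayers(self):
        return list(self.layers)


def _conv_bn_act(cin, cout, k=3, stride=1, rng=None, dtype=np.float32, act="relu"):
    acts = {"relu": ReLU, "relu6": ReLU6}
    return _Seq(Conv2d(cin, cout, k=k, stride=stride, bias=False, rng=rng, dtype=dtype),
                BatchNorm2d(cout, dtype=dtype), acts[act]())


class _MBConv:
    """Inverted-bottleneck block: 1x1 expand -> depthwise -> 1x1 project."""

    def __init__(self, cin, cout, expand, k, stride, use_skip, rng, dtype=np.float32):
        act = ReLU if expand == 1 else ReLU6
        mid = cin * expand
        self.expand = None
        if expand != 1:
            self.expand = _Seq(Conv2d(cin, mid, k=1, bias=False, rng=rng, dtype=dtype),
                               BatchNorm2d(mid, dtype=dtype), act())
        self.dw = _Seq(DepthwiseConv2d(mid, k=k, stride=stride, rng=rng, dtype=dtype),
                       BatchNorm2d(mid, dtype=dtype), act())
        self.project = _Seq(Conv2d(mid, cout, k=1, bias=False, rng=rng, dtype=dtype),
                            BatchNorm2d(cout, dtype=dtype))
        self.skip = use_skip and stride == 1 and cin == cout

    def forward(self, x, train=True):
        h = self.expand.forward(x, train) if self.expand else x
        h = self.dw.forward(h, train)
        h = self.project.forward(h, train)
        return h + x if self.skip else h

    def backward(self, dout):
        dh = self.project.backward(dout)
        dh = self.dw.backward(dh)
        dh = self.expand.backward(dh) if self.expand else dh
        return dh + dout if self.skip else dh

    def sublayers(self):
        out = []
        for seq in (self.expand, self.dw, self.project):
            if seq is not None:
                out.extend(seq.sublayers())
        return out


class _DecoderStage:
    def __init__(self, cin_up, c_skip, cout, rng, dtype=np.float32):
        self.up = Upsample2x()
        self.c_up = cin_up
        self.c_skip = c_skip
        self.conv = _conv_bn_act(cin_up + c_skip, cout, rng=rng, dtype=dtype)

    def forward(self, h, skip, train=True):
        h = self.up.forward(h, train)
        if skip is not None:
            h = np.concatenate([h, skip], axis=1)
        return self.conv.forward(h, train)

    def backward(self, dout):
        dh = self.conv.backward(dout)
        dskip = None
        if self.c_skip:
            dh, dskip = dh[:, :self.c_up], dh[:, self.c_up:]
        return self.up.backward(dh), dskip

    def sublayers(self):
        return self.conv.sublayers()


class SegmentationModel:
    """Full encoder-decoder graph with parameter bookkeeping."""

    def __init__(self, name, stem, stages, skip_stage_ids, stem_is_skip,
                 decoders, head, downsample_factor):
        self.name = name
        self.stem = stem
        self.stages = stages                  # list of lists of blocks
        self.skip_stage_ids = skip_stage_ids  # stage indices feeding decoder skips
        self.stem_is_skip = stem_is_skip
        self.decoders = decoders
        self.head = head
        self.downsample_factor = downsample_factor
        self.trained = False
        self._named = self._collect_named_layers()

    # -- graph ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (B, 1, H, W) input to (B, 3, H, W) class logits."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must have shape (B, 1, H, W)")
        h, w = x.shape[2:]
        d = self.downsample_factor
        if h % d or w % d:
            raise ValueError(f"input size {h}x{w} not divisible by {d}")
        h = self.stem.forward(x, train)
        skips = [h] if self.stem_is_skip else []
        for si, blocks in enumerate(self.stages):
            for blk in blocks:
                h = blk.forward(h, train)
            if si in self.skip_stage_ids:
                skips.append(h)
        self._n_skips = len(skips)
        for di, dec in enumerate(self.decoders):
            skip = skips[-1 - di] if di < len(skips) else None
            h = dec.forward(h, skip, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        skip_grads = {}
        for di in range(len(self.decoders) - 1, -1, -1):
            dh, dskip = self.decoders[di].backward(dh)
            if dskip is not None:
                skip_grads[self._n_skips - 1 - di] = dskip
        # walk the encoder backwards, merging skip gradients at their sources
        skip_slot = self._n_skips - 1
        for si in range(len(self.stages) - 1, -1, -1):
            if si in self.skip_stage_ids:
                if skip_slot in skip_grads:
                    dh = dh + skip_grads[skip_slot]
                skip_slot -= 1
            for blk in reversed(self.stages[si]):
                dh = blk.backward(dh)
        if self.stem_is_skip and 0 in skip_grads:
            dh = dh + skip_grads[0]
        self.stem.backward(dh)

    # -- parameters -------------------------------------------------------

    def _collect_named_layers(self):
        named = []

        def add(prefix, obj):
            for i, lay in enumerate(obj.sublayers()):
                named.append((f"{prefix}.{i}", lay))

        add("stem", self.stem)
        for si, blocks in enumerate(self.stages):
            for bi, blk in enumerate(blocks):
                add(f"enc{si}.{bi}", blk)
        for di, dec in enumerate(self.decoders):
            add(f"dec{di}", dec)
        add("head", self.head)
        return named

    def param_items(self):
        return [(lay, key) for _, lay in self._named for key in lay.params]

    @property
    def num_params(self) -> int:
        return sum(p.size for _, lay in self._named for p in lay.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, lay in self._named:
            for key, val in lay.params.items():
                out[f"{name}/{key}"] = val.copy()
            for key, val in lay.buffers.items():
                out[f"{name}/buf:{key}"] = val.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, lay in self._named:
            for key in lay.params:
                lay.params[key] = state[f"{name}/{key}"].copy()
            for key in lay.buffers:
                lay.buffers[key] = state[f"{name}/buf:{key}"].copy()

    def save(self, path) -> None:
        state = self.state_dict()
        state["__normalization__"] = np.array(
            getattr(self, "normalization", "fixed"))
        np.savez(path, **state)

    def load(self, path) -> None:
        with np.load(path) as z:
            state = {k: z[k] for k in z.files}
        if "__normalization__" in state:
            self.normalization = str(state.pop("__normalization__"))
        self.load_state_dict(state)
        self.trained = True

    def load_encoder_weights(self, path) -> int:
        """Load externally supplied encoder weights (transfer-learning hook).

        Matches parameters by name prefix (``stem.``/``enc``); decoder and
        head weights are untouched.  Returns the number of arrays loaded.
        """
        with np.load(path) as z:
            state = {k: z[k] for k in z.files}
        n = 0
        for name, lay in self._named:
            if not (name.startswith("stem") or name.startswith("enc")):
                continue
            for key in lay.params:
                full = f"{name}/{key}"
                if full in state:
                    if state[full].shape != lay.params[key].shape:
                        raise ValueError(f"shape mismatch for {full}")
                    lay.params[key] = state[full].astype(lay.params[key].dtype)
                    n += 1
        return n


def _build_tiny(rng, dtype):
    chans = [8, 16, 24, 32, 48]
    stem = _conv_bn_act(1, chans[0], rng=rng, dtype=dtype)
    stages = []
    for cin, cout in zip(chans[:-1], chans[1:]):
        stages.append([_conv_bn_act(cin, cout, stride=2, rng=rng, dtype=dtype),
                       _conv_bn_act(cout, cout, rng=rng, dtype=dtype)])
    skip_ids = {0, 1, 2}          # stage outputs at /2, /4, /8 (+ stem at /1)
    dec_specs = [(48, 32, 32), (32, 24, 24), (24, 16, 16), (16, 8, 8)]
    decoders = [_DecoderStage(ci, cs, co, rng, dtype) for ci, cs, co in dec_specs]
    head = _Seq(Conv2d(8, 3, k=1, rng=rng, dtype=dtype))
    return SegmentationModel("tiny", stem, stages, skip_ids, True,
                             decoders, head, downsample_factor=16)


def _build_efficientnet(name, rng, dtype):
    width, depth = _EFF_SCALING[name]
    c_stem = _round_filters(32, width)
    stem = _conv_bn_act(1, c_stem, stride=2, rng=rng, dtype=dtype)
    stages, cin = [], c_stem
    skip_ids = set()
    for si, (expand, c, reps, stride, k) in enumerate(_EFF_STAGES):
        cout = _round_filters(c, width)
        blocks = []
        for r in range(_round_repeats(reps, depth)):
            blocks.append(_MBConv(cin, cout, expand, k,
                                  stride if r == 0 else 1,
                                  use_skip=(r > 0), rng=rng, dtype=dtype))
            cin = cout
        stages.append(blocks)
    # skip sources: last stage output at each of /2, /4, /8, /16
    skip_ids = {0, 1, 2, 4}
    c_skips = [_round_filters(c, width) for c in (16, 24, 40, 112)]
    c_bottom = _round_filters(320, width)
    dec_chans = [96, 64, 48, 32, 24]
    decoders = []
    cin_up = c_bottom
    for di, cout in enumerate(dec_chans):
        c_skip = c_skips[-1 - di] if di < 4 else 0
        decoders.append(_DecoderStage(cin_up, c_skip, cout, rng, dtype))
        cin_up = cout
    head = _Seq(Conv2d(dec_chans[-1], 3, k=1, rng=rng, dtype=dtype))
    return SegmentationModel(name, stem, stages, skip_ids, False,
                             decoders, head, downsample_factor=32)


def build_model(cfg, dtype=np.float32) -> SegmentationModel:
    """Build a segmentation model from a config carrying ``encoder_name``
    and ``seed`` (e.g. :class:`viaphase.net.train.TrainConfig`)."""
    rng = np.random.default_rng(getattr(cfg, "seed", 0))
    name = getattr(cfg, "encoder_name", "tiny").lower()
    if name == "tiny":
        return _build_tiny(rng, dtype)
    if name in _EFF_SCALING:
        return _build_efficientnet(name, rng, dtype)
    raise ValueError(f"unknown encoder '{name}'; choose 'tiny' or 'b0'..'b7'")


def make_optimizer(model: SegmentationModel, cfg) -> Adam:
    return Adam(model.param_items(), lr=cfg.learning_rate,
                beta1=cfg.adam_beta1, beta2=cfg.adam_beta2, eps=cfg.adam_eps)
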