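"""ONNX export and import for the two-branch classifier.

The model is serialised as a genuine ONNX ``ModelProto`` (opset 13)
containing a Conv/Relu/MaxPool/Flatten/Gemm/Concat/Softmax graph with
float32 initializers, written directly in the protobuf wire format.  A
matching parser plus a small numpy graph executor make the file
round-trippable without any external runtime; the graph itself follows
the published operator schemas, with both the raw logits and the
softmax probabilities declared as outputs and the class list stored in
the model metadata.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .classifier import PollenClassifier, Prediction, encode_events
from .errors import ParseError
from .nn import Conv3x3, Dense, softmax

_FLOAT = 1   # TensorProto.DataType
_OPSET = 13


# ---------------------------------------------------------------- writer
def _varint(n: int) -> bytes:
    out = bytearray()
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def _tag(field: int, wire: int) -> bytes:
    return _varint((field << 3) | wire)


def _f_varint(field: int, value: int) -> bytes:
    return _tag(field, 0) + _varint(value)


def _f_bytes(field: int, payload: bytes) -> bytes:
    return _tag(field, 2) + _varint(len(payload)) + payload


def _f_string(field: int, s: str) -> bytes:
    return _f_bytes(field, s.encode())


def _f_packed_ints(field: int, values: Sequence[int]) -> bytes:
    payload = b"".join(_varint(v) for v in values)
    return _f_bytes(field, payload)


def _tensor(name: str, arr: np.ndarray) -> bytes:
    data = np.ascontiguousarray(arr, dtype=np.float32).tobytes()
    return (
        _f_packed_ints(1, arr.shape)        # dims
        + _f_varint(2, _FLOAT)              # data_type
        + _f_string(8, name)                # name
        + _f_bytes(9, data)                 # raw_data
    )


def _attr_ints(name: str, values: Sequence[int]) -> bytes:
    return _f_string(1, name) + _f_packed_ints(8, values) + _f_varint(20, 7)


def _attr_int(name: str, value: int) -> bytes:
    return _f_string(1, name) + _f_varint(3, value) + _f_varint(20, 2)


def _node(op: str, inputs: Sequence[str], outputs: Sequence[str],
          attrs: Sequence[bytes] = ()) -> bytes:
    buf = b"".join(_f_string(1, i) for i in inputs)
    buf += b"".join(_f_string(2, o) for o in outputs)
    buf += _f_string(4, op)
    buf += b"".join(_f_bytes(5, a) for a in attrs)
    return buf


def _value_info(name: str, dims: Sequence) -> bytes:
    shape = b""
    for d in dims:
        if isinstance(d, str):
            shape += _f_bytes(1, _f_string(2, d))
        else:
            shape += _f_bytes(1, _f_varint(1, d))
    tensor_type = _f_varint(1, _FLOAT) + _f_bytes(2, shape)
    return _f_string(1, name) + _f_bytes(2, _f_bytes(1, tensor_type))


def _graph_bytes(model: PollenClassifier) -> bytes:
    cfg = model.config
    net = model.net
    nodes: List[bytes] = []
    inits: List[bytes] = []
    x = "image"
    conv_i = 0
    for layer in net.image_branch.layers:
        if isinstance(layer, Conv3x3):
            w, b = f"conv{conv_i}_w", f"conv{conv_i}_b"
            inits += [_tensor(w, layer.w.value), _tensor(b, layer.b.value)]
            out = f"conv{conv_i}_out"
            nodes.append(_node("Conv", [x, w, b], [out], [
                _attr_ints("kernel_shape", [3, 3]),
                _attr_ints("pads", [1, 1, 1, 1]),
                _attr_ints("strides", [1, 1]),
            ]))
            x = out
            conv_i += 1
        elif type(layer).__name__ == "ReLU":
            out = x + "_relu"
            nodes.append(_node("Relu", [x], [out]))
            x = out
        elif type(layer).__name__ == "MaxPool2":
            out = x + "_pool"
            nodes.append(_node("MaxPool", [x], [out], [
                _attr_ints("kernel_shape", [2, 2]),
                _attr_ints("strides", [2, 2]),
            ]))
            x = out
        elif type(layer).__name__ == "Flatten":
            out = "img_flat"
            nodes.append(_node("Flatten", [x], [out], [_attr_int("axis", 1)]))
            x = out
        elif isinstance(layer, Dense):
            w, b = "img_dense_w", "img_dense_b"
            inits += [_tensor(w, layer.w.value), _tensor(b, layer.b.value)]
            nodes.append(_node("Gemm", [x, w, b], ["img_feat_pre"],
                               [_attr_int("transB", 1)]))
            x = "img_feat_pre"
    img_feat = x  # last relu output name
    fl_dense = net.fluor_branch.layers[0]
    inits += [_tensor("fluor_w", fl_dense.w.value),
              _tensor("fluor_b", fl_dense.b.value)]
    nodes.append(_node("Gemm", ["fluorescence", "fluor_w", "fluor_b"],
                       ["fluor_pre"], [_attr_int("transB", 1)]))
    nodes.append(_node("Relu", ["fluor_pre"], ["fluor_feat"]))
    nodes.append(_node("Concat", [img_feat, "fluor_feat"], ["fused"],
                       [_attr_int("axis", 1)]))
    inits += [_tensor("head_w", net.head.w.value),
              _tensor("head_b", net.head.b.value)]
    nodes.append(_node("Gemm", ["fused", "head_w", "head_b"], ["logits"],
                       [_attr_int("transB", 1)]))
    nodes.append(_node("Softmax", ["logits"], ["probs"],
                       [_attr_int("axis", 1)]))

    side = cfg.image_side
    graph = b"".join(_f_bytes(1, n) for n in nodes)
    graph += _f_string(2, "holopollen_two_branch")
    graph += b"".join(_f_bytes(5, t) for t in inits)
    graph += _f_bytes(11, _value_info("image", ["N", 2, side, side]))
    graph += _f_bytes(11, _value_info("fluorescence", ["N", 14]))
    graph += _f_bytes(12, _value_info("logits", ["N", len(cfg.class_names)]))
    graph += _f_bytes(12, _value_info("probs", ["N", len(cfg.class_names)]))
    return graph


def export_model(model: Union[PollenClassifier, "object"], path) -> None:
    """Serialise a (trained or initialised) classifier as an ONNX file."""
    if hasattr(model, "model"):  # ClassifierFit
        model = model.model
    cfg = model.config
    meta = {
        "class_names": list(cfg.class_names),
        "image_side": cfg.image_side,
        "conv_blocks": [list(b) for b in cfg.conv_blocks],
        "fluor_hidden_units": cfg.fluor_hidden_units,
        "image_features": cfg.image_features,
        "droplet_class": cfg.droplet_class,
    }
    buf = _f_varint(1, 8)                               # ir_version
    buf += _f_string(2, "holopollen")                   # producer_name
    buf += _f_bytes(7, _graph_bytes(model))             # graph
    buf += _f_bytes(8, _f_varint(2, _OPSET))            # opset_import
    buf += _f_bytes(14, _f_string(1, "holopollen_config")
                    + _f_string(2, json.dumps(meta)))   # metadata_props
    Path(path).write_bytes(buf)


# ---------------------------------------------------------------- parser
def _parse_message(buf: bytes) -> Dict[int, list]:
    """Decode one protobuf message into {field: [(wire_type, value), ...]}."""
    fields: Dict[int, list] = {}
    i, n = 0, len(buf)

    def read_varint():
        nonlocal i
        shift, val = 0, 0
        while True:
            if i >= n:
                raise ParseError("truncated varint in model file")
            b = buf[i]
            i += 1
            val |= (b & 0x7F) << shift
            if not b & 0x80:
                return val
            shift += 7

    while i < n:
        key = read_varint()
        field, wire = key >> 3, key & 7
        if wire == 0:
            val = read_varint()
        elif wire == 2:
            length = read_varint()
            if i + length > n:
                raise ParseError("truncated length-delimited field")
            val = buf[i:i + length]
            i += length
        elif wire == 5:
            if i + 4 > n:
                raise ParseError("truncated 32-bit field")
            val = struct.unpack("<f", buf[i:i + 4])[0]
            i += 4
        elif wire == 1:
            if i + 8 > n:
                raise ParseError("truncated 64-bit field")
            val = struct.unpack("<d", buf[i:i + 8])[0]
            i += 8
        else:
            raise ParseError(f"unsupported protobuf wire type {wire}")
        fields.setdefault(field, []).append((wire, val))
    return fields


def _unpack_ints(payload: bytes) -> List[int]:
    out, i = [], 0
    while i < len(payload):
        shift, val = 0, 0
        while True:
            b = payload[i]
            i += 1
            val |= (b & 0x7F) << shift
            if not b & 0x80:
                break
            shift += 7
        out.append(val)
    return out


def _parse_tensor(buf: bytes) -> Tuple[str, np.ndarray]:
    f = _parse_message(buf)
    dims = _unpack_ints(f[1][0][1]) if 1 in f else []
    name = f[8][0][1].decode()
    arr = np.frombuffer(f[9][0][1], dtype=np.float32).reshape(dims)
    return name, arr


def _parse_attrs(node_fields) -> Dict[str, object]:
    attrs = {}
    for _, payload in node_fields.get(5, []):
        a = _parse_message(payload)
        name = a[1][0][1].decode()
        if 8 in a:
            attrs[name] = _unpack_ints(a[8][0][1])
        elif 3 in a:
            attrs[name] = a[3][0][1]
    return attrs


class OnnxClassifier:
    """A classifier reloaded from an ONNX file, executed with numpy."""

    def __init__(self, nodes, initializers, meta):
        self.nodes = nodes
        self.initializers = initializers
        self.meta = meta
        self.class_names = tuple(meta["class_names"])
        self.image_side = meta["image_side"]

    def run(self, images: np.ndarray, fluor: np.ndarray) -> Dict[str, np.ndarray]:
        env = dict(self.initializers)
        env["image"] = np.asarray(images, dtype=np.float32)
        env["fluorescence"] = np.asarray(fluor, dtype=np.float32)
        for op, inputs, outputs, attrs in self.nodes:
            if op == "Conv":
                x, w, b = (env[i] for i in inputs)
                if attrs.get("kernel_shape") != [3, 3] or attrs.get("pads") != [1, 1, 1, 1]:
                    raise ParseError(f"unsupported Conv attributes {attrs}")
                nb, c, h, wd = x.shape
                xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
                cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
                cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(nb * h * wd, c * 9)
                cout = w.shape[0]
                out = cols @ w.reshape(cout, c * 9).T + b
                env[outputs[0]] = out.reshape(nb, h, wd, cout).transpose(0, 3, 1, 2)
            elif op == "Relu":
                env[outputs[0]] = np.maximum(env[inputs[0]], 0.0)
            elif op == "MaxPool":
                x = env[inputs[0]]
                nb, c, h, wd = x.shape
                env[outputs[0]] = x.reshape(
                    nb, c, h // 2, 2, wd // 2, 2
                ).max(axis=(3, 5))
            elif op == "Flatten":
                x = env[inputs[0]]
                env[outputs[0]] = x.reshape(x.shape[0], -1)
            elif op == "Gemm":
                a, w, b = (env[i] for i in inputs)
                env[outputs[0]] = a @ w.T + b
            elif op == "Concat":
                env[outputs[0]] = np.concatenate(
                    [env[i] for i in inputs], axis=int(attrs.get("axis", 1))
                )
            elif op == "Softmax":
                env[outputs[0]] = softmax(env[inputs[0]])
            else:
                raise ParseError(f"unsupported operator {op!r} in graph")
        return env

    def predict_logits(self, images: np.ndarray, fluor: np.ndarray) -> np.ndarray:
        return self.run(images, fluor)["logits"]

    def predict(self, events) -> List[Prediction]:
        images, fluor = encode_events(events, self.image_side)
        out = self.run(images, fluor)
        return [
            Prediction(ev.event_id, p, self.class_names)
            for ev, p in zip(events, out["probs"])
        ]


def load_model(path) -> OnnxClassifier:
    """Parse an ONNX file written by :func:`export_model`."""
    buf = Path(path).read_bytes()
    model = _parse_message(buf)
    if 7 not in model:
        raise ParseError(f"{path}: no graph found in model file")
    graph = _parse_message(model[7][0][1])
    initializers = dict(
        _parse_tensor(payload) for _, payload in graph.get(5, [])
    )
    nodes = []
    for _, payload in graph.get(1, []):
        f = _parse_message(payload)
        op = f[4][0][1].decode()
        inputs = [v.decode() for _, v in f.get(1, [])]
        outputs = [v.decode() for _, v in f.get(2, [])]
        nodes.append((op, inputs, outputs, _parse_attrs(f)))
    meta = None
    for _, payload in model.get(14, []):
        entry = _parse_message(payload)
        if entry[1][0][1].decode() == "holopollen_config":
            meta = json.loads(entry[2][0][1].decode())
    if meta is None:
        raise ParseError(f"{path}: missing holopollen_config metadata")
    return OnnxClassifier(nodes, initializers, meta)
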