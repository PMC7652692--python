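"""WeightSet: ordered named tensors, the unit of client-server exchange."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["WeightSet", "encode_payload", "decode_payload"]


@dataclass
class WeightSet:
    """Ordered, named parameter tensors of one model instance.

    Two WeightSets of the same :class:`~fedbench.models.ModelSpec` share
    names, order and shapes, so element-wise arithmetic (averaging) is well
    defined. ``fingerprint`` identifies the producing architecture.
    """

    names: tuple[str, ...]
    tensors: dict[str, np.ndarray]
    fingerprint: str

    def __post_init__(self) -> None:
        if set(self.names) != set(self.tensors):
            raise ValueError("names and tensors disagree")

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.names, {k: v.copy() for k, v in self.tensors.items()}, self.fingerprint
        )

    def shapes(self) -> dict[str, tuple[int, ...]]:
        return {k: tuple(self.tensors[k].shape) for k in self.names}

    def compatible_with(self, other: "WeightSet") -> bool:
        return self.names == other.names and self.shapes() == other.shapes()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.tensors[name]

    def allclose(self, other: "WeightSet", rtol=1e-7, atol=1e-12) -> bool:
        return self.compatible_with(other) and all(
            np.allclose(self.tensors[k], other.tensors[k], rtol=rtol, atol=atol)
            for k in self.names
        )

    def equal(self, other: "WeightSet") -> bool:
        """Bit-exact equality."""
        return self.compatible_with(other) and all(
            np.array_equal(self.tensors[k], other.tensors[k]) for k in self.names
        )

    def to_payload(self) -> dict:
        """JSON-able wire form: a list of named, shaped, flattened tensors.

        Floats are emitted through Python's shortest round-trip repr, so the
        payload decodes back to bit-identical float64 (hence also float32)
        tensors.
        """
        return {
            "fingerprint": self.fingerprint,
            "tensors": [
                {
                    "name": k,
                    "shape": list(self.tensors[k].shape),
                    "values": [float(v) for v in self.tensors[k].ravel()],
                }
                for k in self.names
            ],
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "WeightSet":
        names, tensors = [], {}
        for entry in payload["tensors"]:
            name = entry["name"]
            arr = np.array(entry["values"], dtype=np.float64).reshape(entry["shape"])
            names.append(name)
            tensors[name] = arr
        return cls(tuple(names), tensors, payload["fingerprint"])


def encode_payload(payload: dict) -> bytes:
    """Canonical JSON bytes (sorted keys, no whitespace): re-encoding a
    decoded payload reproduces the exact bytes, so equality is testable."""
    return json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()


def decode_payload(data: bytes) -> dict:
    return json.loads(data.decode())
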