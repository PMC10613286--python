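"""Language models as code-length oracles.

Two backends are shipped:

* ``ppm`` — an adaptive variable-order Markov model (prediction by partial
  matching) with method-C escapes: at each context the escape probability is
  ``d / (n + d)`` where ``n`` is the context count total and ``d`` the
  number of distinct successors.  Prediction mixes orders ``o, o-1, ..., 0``
  and finally a uniform base distribution; the reported quantity is the
  ideal arithmetic-coding length ``sum_t -log2 p_t(x_t)``, which differs
  from an actual arithmetic coder's output by O(1) bits.
* ``lzma`` — a dictionary coder adapter; bits are eight times the length of
  the compressed byte stream at the maximum preset.

Any callable mapping a byte stream to a bit count can be registered as an
additional backend, which is how external compressors plug in.
"""

from __future__ import annotations

import lzma
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

# counts arrays beyond this many cells fall back to the dict implementation
_FAST_PATH_MAX_CELLS = 50_000_000


@dataclass
class CompressorConfig:
    """Backend choice and PPM context order.

    ``base_alphabet_size`` is the support of the final uniform back-off
    level; ``None`` means the 4-byte code universe (2**32) for symbol-id
    streams and 256 for byte streams.  ``memory_cap`` bounds the number of
    distinct contexts the model may allocate (freeze-on-full).
    """

    backend: str = "ppm"
    order: int = 2
    memory_cap: int | None = None
    base_alphabet_size: int | None = None

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")


@dataclass
class LearningCurve:
    """Incremental compression rates: (l, r_l) at increasing prefix lengths."""

    document: str
    level: str
    lengths: np.ndarray  # l, strictly increasing, last = L
    rates: np.ndarray  # r_l = bits to compress first l symbols, divided by l

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.lengths) != len(self.rates):
            raise ValueError("lengths/rates size mismatch")
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("checkpoint lengths must be strictly increasing")

    @property
    def L(self) -> int:
        return int(self.lengths[-1])


@njit(cache=False)
def _ppm_bits_fast(seq, V, order, counts, totals, distinct, offsets, base_p, update, out):
    n = seq.shape[0]
    for t in range(n):
        x = seq[t]
        kmax = min(order, t)
        p = 0.0
        esc = 1.0
        # mix predictions from the longest available context down to order 0
        for k in range(kmax, -1, -1):
            code = 0
            mult = 1
            for j in range(1, k + 1):
                code += seq[t - j] * mult
                mult *= V
            row = offsets[k] + code
            tot = totals[row]
            if tot > 0:
                d = distinct[row]
                denom = tot + d
                p += esc * counts[row, x] / denom
                esc *= d / denom
        p += esc * base_p
        out[t] = -np.log2(p)
        if update:
            for k in range(kmax + 1):
                code = 0
                mult = 1
                for j in range(1, k + 1):
                    code += seq[t - j] * mult
                    mult *= V
                row = offsets[k] + code
                if counts[row, x] == 0:
                    distinct[row] += 1
                counts[row, x] += 1
                totals[row] += 1


class PPMModel:
    """Stateful PPM code-length oracle over integer symbol ids ``0..V-1``.

    Small state spaces (``sum_k V**(k+1)`` cells) use flat numpy count
    arrays driven by a numba kernel; larger ones use a dict-of-counts
    fallback with an optional context-node budget (new contexts are no
    longer allocated once the budget is exhausted; existing ones keep
    adapting).
    """

    def __init__(
        self,
        alphabet_size: int,
        order: int = 2,
        base_alphabet_size: int | None = None,
        memory_cap: int | None = None,
    ) -> None:
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        if order < 0:
            raise ValueError("order must be >= 0")
        self.V = int(alphabet_size)
        self.order = int(order)
        self.base_alphabet_size = int(base_alphabet_size or max(self.V, 2))
        if self.base_alphabet_size < self.V:
            raise ValueError("base alphabet smaller than stream alphabet")
        self.memory_cap = memory_cap
        n_rows = 0
        cells = 0
        offsets = [0]
        for k in range(self.order + 1):
            n_rows += self.V**k
            offsets.append(n_rows)
            cells = n_rows * self.V
        self._fast = cells <= _FAST_PATH_MAX_CELLS and memory_cap is None
        if self._fast:
            self._offsets = np.asarray(offsets[:-1], dtype=np.int64)
            self._counts = np.zeros((n_rows, self.V), dtype=np.int32)
            self._totals = np.zeros(n_rows, dtype=np.int64)
            self._distinct = np.zeros(n_rows, dtype=np.int32)
        else:
            # per order: context-code -> {symbol: count}
            self._ctx: list[dict[int, dict[int, int]]] = [
                {} for _ in range(self.order + 1)
            ]
            self._n_nodes = 0

    # -- state management ---------------------------------------------------

    def _snapshot(self):
        if self._fast:
            return self._counts.copy(), self._totals.copy(), self._distinct.copy()
        return [{c: dict(d) for c, d in lvl.items()} for lvl in self._ctx], self._n_nodes

    def _restore(self, snap) -> None:
        if self._fast:
            self._counts, self._totals, self._distinct = snap
        else:
            self._ctx, self._n_nodes = snap

    # -- coding -------------------------------------------------------------

    def feed(self, ids: np.ndarray) -> np.ndarray:
        """Encode ``ids`` adaptively, updating the model; per-position bits."""
        return self._run(np.ascontiguousarray(ids, dtype=np.int64), update=True)

    def peek(self, ids: np.ndarray) -> np.ndarray:
        """Encode ``ids`` adaptively but leave the model state unchanged.

        The model still adapts *within* ``ids`` (as it would when the
        segment is appended to the training stream), matching
        ``R(train + ids) - R(train)``.
        """
        snap = self._snapshot()
        bits = self._run(np.ascontiguousarray(ids, dtype=np.int64), update=True)
        self._restore(snap)
        return bits

    def _run(self, seq: np.ndarray, update: bool) -> np.ndarray:
        if seq.size and (seq.min() < 0 or seq.max() >= self.V):
            raise ValueError("symbol id out of range")
        out = np.empty(seq.shape[0], dtype=np.float64)
        base_p = 1.0 / self.base_alphabet_size
        if self._fast:
            _ppm_bits_fast(
                seq, self.V, self.order, self._counts, self._totals,
                self._distinct, self._offsets, base_p, update, out,
            )
            return out
        return self._run_dict(seq, update, out, base_p)

    def _run_dict(self, seq: np.ndarray, update: bool, out: np.ndarray, base_p: float) -> np.ndarray:
        V = self.V
        for t in range(seq.shape[0]):
            x = int(seq[t])
            kmax = min(self.order, t)
            p = 0.0
            esc = 1.0
            codes = []
            for k in range(kmax + 1):
                code = 0
                mult = 1
                for j in range(1, k + 1):
                    code += int(seq[t - j]) * mult
                    mult *= V
                codes.append(code)
            for k in range(kmax, -1, -1):
                node = self._ctx[k].get(codes[k])
                if node:
                    tot = sum(node.values())
                    d = len(node)
                    denom = tot + d
                    p += esc * node.get(x, 0) / denom
                    esc *= d / denom
            p += esc * base_p
            out[t] = -np.log2(p)
            if update:
                for k in range(kmax + 1):
                    node = self._ctx[k].get(codes[k])
                    if node is None:
                        if self.memory_cap is not None and self._n_nodes >= self.memory_cap:
                            continue  # frozen: budget exhausted
                        node = self._ctx[k][codes[k]] = {}
                        self._n_nodes += 1
                    node[x] = node.get(x, 0) + 1
        return out

    def predictive_distribution(self, context: Sequence[int]) -> np.ndarray:
        """p(x | context) over ``0..V-1`` (diagnostic; sums to the modeled
        mass, exactly 1 when base_alphabet_size == V)."""
        probe = np.asarray(list(context), dtype=np.int64)
        snap = self._snapshot()
        probs = np.empty(self.V)
        for x in range(self.V):
            seq = np.append(probe, x)
            bits = self._run(seq, update=False)
            probs[x] = 2.0 ** (-bits[-1])
        self._restore(snap)
        return probs


# ---------------------------------------------------------------------------
# module-level operations


def _as_ids(stream) -> tuple[np.ndarray, int, int]:
    """Normalize a byte or symbol-id stream to (ids, V, default base alphabet)."""
    if isinstance(stream, (bytes, bytearray)):
        ids = np.frombuffer(bytes(stream), dtype=np.uint8).astype(np.int64)
        return ids, 256, 256
    ids = np.asarray(stream, dtype=np.int64)
    if ids.size == 0:
        return ids, 1, 2**32
    return ids, int(ids.max()) + 1, 2**32


def ppm_codelength(
    stream,
    config: CompressorConfig | None = None,
    return_per_position: bool = False,
):
    """Ideal PPM code length ``sum_t -log2 p_t(x_t)`` of a stream.

    ``stream`` may be bytes (alphabet 256) or a sequence of integer symbol
    ids.  Deterministic; 0.0 for empty input.
    """
    config = config or CompressorConfig()
    ids, V, base_default = _as_ids(stream)
    if ids.size == 0:
        return (0.0, np.empty(0)) if return_per_position else 0.0
    model = PPMModel(
        V,
        order=config.order,
        base_alphabet_size=config.base_alphabet_size or base_default,
        memory_cap=config.memory_cap,
    )
    bits = model.feed(ids)
    total = float(bits.sum())
    return (total, bits) if return_per_position else total


def lzma_bits(stream: bytes) -> float:
    """Bits of the lzma-compressed stream at the maximum preset."""
    return 8.0 * len(lzma.compress(bytes(stream), preset=9 | lzma.PRESET_EXTREME))


_BACKENDS: dict[str, Callable[[bytes], float]] = {
    "lzma": lzma_bits,
    "lzma-adapter": lzma_bits,
}


def register_backend(name: str, fn: Callable[[bytes], float]) -> None:
    """Register a callable byte-stream -> bit-count backend."""
    _BACKENDS[name] = fn


def backend_codelength(stream: bytes, backend: str = "lzma") -> float:
    """Bit count of a registered external backend on a byte stream."""
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend: {backend!r}") from None
    return float(fn(bytes(stream)))


def compression_curve(
    stream,
    config: CompressorConfig | None = None,
    n_checkpoints: int = 20,
    document: str = "",
    level: str = "word",
) -> LearningCurve:
    """Compression rate ``r_l`` at ``n_checkpoints`` evenly spaced prefixes.

    Checkpoints sit at ``l = round(k * L / n_checkpoints)``; the default 20
    checkpoints place one every 5% of the document.  For the PPM backend the
    model is trained once incrementally so all prefixes share computation;
    external backends compress each prefix separately.
    """
    config = config or CompressorConfig()
    ids, _, _ = _as_ids(stream)
    L = ids.size
    if L < n_checkpoints:
        raise ValueError(f"document of length {L} shorter than {n_checkpoints} checkpoints")
    lengths = np.unique(np.round(np.arange(1, n_checkpoints + 1) * L / n_checkpoints).astype(np.int64))
    lengths = lengths[lengths > 0]
    if config.backend == "ppm":
        _, bits = ppm_codelength(stream, config, return_per_position=True)
        cum = np.cumsum(bits)
        rates = cum[lengths - 1] / lengths
    else:
        if not isinstance(stream, (bytes, bytearray)):
            raise ValueError("external backends require a byte stream")
        data = bytes(stream)
        rates = np.array(
            [backend_codelength(data[:l], config.backend) / l for l in lengths]
        )
    return LearningCurve(document=document, level=level, lengths=lengths, rates=rates)
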