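"""Quasi-random stimulus streams and required-response (target) sequences.

The environment is a discrete stream over the two-bit signal alphabet
pause = (0,0), A = (1,0), B = (0,1), C = (1,1).  A recognition task such as
A3 or C4 names the "correct" stimulus and the number of processing ticks
(the response window) the network is given: after an occurrence of the
correct stimulus the required response is (1,1) for exactly ``window``
ticks starting one tick after the stimulus, and (0,0) everywhere else.

Stimuli are single-tick pulses drawn uniformly from {A, B, C}, separated
by pauses of uniformly random length; a pause is extended when necessary
so that the next stimulus never arrives while a response window is still
open (windows never overlap).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Signal",
    "TaskSpec",
    "StreamConfig",
    "StimulusAnnotation",
    "EventStream",
    "generate_stream",
    "swap_AB",
    "fixture_stream",
    "stream_to_text",
    "stream_from_text",
]


class Signal(enum.Enum):
    """The four stream symbols and their two-bit input codes."""

    PAUSE = (0, 0)
    A = (1, 0)
    B = (0, 1)
    C = (1, 1)

    @property
    def code(self) -> tuple[int, int]:
        return self.value

    @classmethod
    def from_code(cls, code: tuple[int, int]) -> "Signal":
        for s in cls:
            if s.value == tuple(code):
                return s
        raise ValueError(f"no signal with code {code!r}")


_STIMULI = (Signal.A, Signal.B, Signal.C)


@dataclass(frozen=True)
class TaskSpec:
    """A recognition function: which stimulus is correct and the window length.

    The name concatenates the two, e.g. ``A3`` = respond (1,1) within a
    3-tick window to stimulus A, ``C4`` = a 4-tick window for stimulus C.
    C-tasks are symmetric under swapping the two input lines, which doubles
    the functional-symmetry group (see :mod:`nnmo.symmetry`).
    """

    correct_signal: Signal
    window: int

    def __post_init__(self) -> None:
        if self.correct_signal is Signal.PAUSE:
            raise ValueError("the correct signal cannot be the pause")
        if self.window not in (3, 4):
            raise ValueError("window must be 3 or 4 ticks")

    @property
    def name(self) -> str:
        return f"{self.correct_signal.name}{self.window}"

    @classmethod
    def from_name(cls, name: str) -> "TaskSpec":
        name = name.strip().upper()
        if len(name) != 2 or name[0] not in "ABC" or not name[1].isdigit():
            raise ValueError(f"malformed task name {name!r} (expected e.g. 'A3', 'C4')")
        return cls(Signal[name[0]], int(name[1]))

    @property
    def input_swap_symmetric(self) -> bool:
        """True when the task is invariant under swapping the two input lines."""
        return self.correct_signal is Signal.C


# Module-level defaults for the standard protocol: 100-symbol fragments,
# single-tick stimuli, pauses uniform on 1..4 ticks.
DEFAULT_LENGTH_SYMBOLS = 100
DEFAULT_PAUSE_MIN = 1
DEFAULT_PAUSE_MAX = 4


@dataclass(frozen=True)
class StreamConfig:
    """Parameters of stream generation.

    ``pause_min``/``pause_max`` bound the drawn inter-stimulus pause in
    ticks; the effective pause is extended to the response window when the
    draw is shorter, so that windows never overlap the next stimulus.
    """

    length_symbols: int = DEFAULT_LENGTH_SYMBOLS
    pause_min: int = DEFAULT_PAUSE_MIN
    pause_max: int = DEFAULT_PAUSE_MAX
    stimulus_ticks: int = 1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.pause_min <= self.pause_max):
            raise ValueError("need 1 <= pause_min <= pause_max")
        if self.stimulus_ticks < 1 or self.length_symbols < 1:
            raise ValueError("stimulus_ticks and length_symbols must be >= 1")


@dataclass(frozen=True)
class StimulusAnnotation:
    """One stimulus occurrence: its symbol, onset tick, and response window."""

    signal: Signal
    onset: int
    window: int


@dataclass
class EventStream:
    """Paired per-tick input and target sequences with per-stimulus annotations."""

    inputs: np.ndarray  # (T, 2) int8
    targets: np.ndarray  # (T, 2) int8
    annotations: tuple[StimulusAnnotation, ...]
    task: TaskSpec
    config: StreamConfig | None = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.int8)
        self.targets = np.asarray(self.targets, dtype=np.int8)
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must have equal shape")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_symbols(self) -> int:
        return len(self.annotations)


def _assemble(
    symbols: list[Signal],
    gaps: list[int],
    task: TaskSpec,
    cfg: StreamConfig | None,
) -> EventStream:
    """Lay out stimuli and pauses into per-tick input/target arrays.

    ``gaps[k]`` is the number of pause ticks after symbol ``k``; a final
    window-length pause is appended so the last response window is always
    contained in the stream.
    """
    st = cfg.stimulus_ticks if cfg is not None else 1
    onsets = []
    t = 0
    for k in range(len(symbols)):
        onsets.append(t)
        t += st + gaps[k]
    total = t  # each gap >= window for generated streams, so windows fit
    inputs = np.zeros((total, 2), dtype=np.int8)
    targets = np.zeros((total, 2), dtype=np.int8)
    annotations = []
    for sym, onset in zip(symbols, onsets):
        for s in range(st):
            inputs[onset + s] = sym.code
        if sym is task.correct_signal:
            lo = onset + st
            hi = min(lo + task.window, total)
            targets[lo:hi] = 1
        annotations.append(StimulusAnnotation(sym, onset, task.window))
    return EventStream(inputs, targets, tuple(annotations), task, cfg)


_CODES = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)  # A, B, C


def generate_stream(
    task: TaskSpec,
    cfg: StreamConfig | None = None,
    rng: np.random.Generator | None = None,
    annotate: bool = True,
) -> EventStream:
    """Generate a quasi-random stream of ``length_symbols`` stimuli.

    Stimulus types are i.i.d. uniform on {A, B, C}; pause draws are i.i.d.
    uniform integers on [pause_min, pause_max].  The effective gap after a
    stimulus is ``max(pause, window)`` so that the response window closes
    before the next stimulus.  Deterministic given ``cfg.rng_seed`` (or an
    explicit generator, which takes precedence).  ``annotate=False`` skips
    building the per-stimulus annotation records (used by the hot training
    loop; the tick arrays are identical either way).
    """
    cfg = cfg or StreamConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.length_symbols
    syms = rng.integers(0, 3, size=n)
    pauses = rng.integers(cfg.pause_min, cfg.pause_max + 1, size=n)
    if cfg.stimulus_ticks != 1:
        symbols = [_STIMULI[i] for i in syms]
        gaps = [max(int(p), task.window) for p in pauses]
        return _assemble(symbols, gaps, task, cfg)
    gaps = np.maximum(pauses, task.window)
    strides = 1 + gaps
    onsets = np.concatenate(([0], np.cumsum(strides[:-1])))
    total = int(onsets[-1] + strides[-1])
    inputs = np.zeros((total, 2), dtype=np.int8)
    targets = np.zeros((total, 2), dtype=np.int8)
    inputs[onsets] = _CODES[syms]
    correct = _STIMULI.index(task.correct_signal)
    hits = onsets[syms == correct]
    if hits.size:
        idx = (hits[:, None] + np.arange(1, task.window + 1)).ravel()
        targets[idx] = 1
    if annotate:
        annotations = tuple(
            StimulusAnnotation(_STIMULI[s], int(o), task.window)
            for s, o in zip(syms, onsets)
        )
    else:
        annotations = ()
    return EventStream(inputs, targets, annotations, task, cfg)


def swap_AB(stream: EventStream) -> EventStream:
    """Swap the two input lines: every input pair (p, q) becomes (q, p).

    Targets are untouched; A and B annotations swap, C and pause are fixed
    (their codes are symmetric).  This is the environment-side half of the
    input-neuron permutation symmetry of C-tasks.
    """
    swapped = stream.inputs[:, ::-1].copy()
    flip = {Signal.A: Signal.B, Signal.B: Signal.A}
    annotations = tuple(
        StimulusAnnotation(flip.get(a.signal, a.signal), a.onset, a.window)
        for a in stream.annotations
    )
    return EventStream(swapped, stream.targets.copy(), annotations, stream.task, stream.config)


# ---------------------------------------------------------------------------
# Fixtures: tiny hard-coded streams for unit tests
# ---------------------------------------------------------------------------

_FIXTURES: dict[str, tuple[str, str, tuple[int, ...]]] = {
    # name -> (task name, symbol string, gap per symbol)
    "a3_tiny": ("A3", "ABACB", (3, 4, 3, 3, 3)),
    "c4_tiny": ("C4", "CABCA", (4, 4, 5, 4, 4)),
}


def fixture_stream(name: str) -> EventStream:
    """A small deterministic stream from the documented fixture registry."""
    try:
        task_name, syms, gaps = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    task = TaskSpec.from_name(task_name)
    return _assemble([Signal[c] for c in syms], list(gaps), task, None)


# ---------------------------------------------------------------------------
# Serialization: plain text, one tick per line
# ---------------------------------------------------------------------------


def stream_to_text(stream: EventStream) -> str:
    """Serialize a stream: header block, then one ``in0 in1 tgt0 tgt1`` line per tick."""
    buf = io.StringIO()
    buf.write(f"# task: {stream.task.name}\n")
    if stream.config is not None:
        c = stream.config
        buf.write(
            f"# config: length_symbols={c.length_symbols} pause_min={c.pause_min} "
            f"pause_max={c.pause_max} stimulus_ticks={c.stimulus_ticks} "
            f"rng_seed={c.rng_seed}\n"
        )
    buf.write(
        "# annotations: "
        + ";".join(f"{a.signal.name},{a.onset},{a.window}" for a in stream.annotations)
        + "\n"
    )
    for (i0, i1), (t0, t1) in zip(stream.inputs, stream.targets):
        buf.write(f"{i0} {i1} {t0} {t1}\n")
    return buf.getvalue()


def stream_from_text(text: str) -> EventStream:
    """Inverse of :func:`stream_to_text`; the round trip is exact."""
    task = None
    config = None
    annotations: tuple[StimulusAnnotation, ...] = ()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("# task:"):
            task = TaskSpec.from_name(line.split(":", 1)[1])
        elif line.startswith("# config:"):
            kv = dict(p.split("=") for p in line.split(":", 1)[1].split())
            config = StreamConfig(
                length_symbols=int(kv["length_symbols"]),
                pause_min=int(kv["pause_min"]),
                pause_max=int(kv["pause_max"]),
                stimulus_ticks=int(kv["stimulus_ticks"]),
                rng_seed=None if kv["rng_seed"] == "None" else int(kv["rng_seed"]),
            )
        elif line.startswith("# annotations:"):
            body = line.split(":", 1)[1].strip()
            if body:
                annotations = tuple(
                    StimulusAnnotation(Signal[s], int(o), int(w))
                    for s, o, w in (item.split(",") for item in body.split(";"))
                )
        elif line.startswith("#"):
            continue
        else:
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            rows.append([int(p) for p in parts])
    if task is None:
        raise ValueError("missing '# task:' header")
    data = np.asarray(rows, dtype=np.int8).reshape(-1, 4)
    return EventStream(data[:, :2], data[:, 2:], annotations, task, config)
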