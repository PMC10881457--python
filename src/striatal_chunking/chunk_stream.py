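"""Synthetic chunked character streams and their one-hot input encoding.

The model's task is sequence chunking: a continuous stream of discrete
characters in which a fixed multi-character word (the *chunk*) recurs
among background (distractor) characters.  Characters are presented one
per epoch of fixed duration and encoded as one-hot currents onto the
input units, so a stream of ``E`` epochs at timestep ``dt`` becomes an
``(E * char_duration / dt, alphabet_size)`` current matrix.  The time
interval of every full chunk presentation (a *chunk window*) is recorded,
because readout peaks are later scored by their latency relative to
chunk onset.

Distractor characters are drawn uniformly from the part of the alphabet
not used by the chunk, one character at a time, so the chunk word is the
only repeated multi-character structure in the stream.  Chunk emissions
never overlap: the emitter is epoch-serial and either appends the whole
chunk word or a single distractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChunkProtocol",
    "InputSignal",
    "ProtocolError",
    "EncodingError",
    "generate_sequence",
    "encode_one_hot",
    "generate_input",
    "find_chunk_windows",
    "write_stream",
    "write_windows",
]


class ProtocolError(ValueError):
    """The chunk protocol is internally inconsistent."""


class EncodingError(ValueError):
    """A character log cannot be one-hot encoded under the protocol."""


@dataclass(frozen=True)
class ChunkProtocol:
    """Statistics of the synthetic character stream.

    Parameters
    ----------
    alphabet_size
        Number of distinct characters (= number of one-hot input units).
    chunk
        The embedded chunk word as an ordered tuple of character indices.
    char_duration
        Presentation time of one character, in ms.
    chunk_rate
        Probability that the next emission is the full chunk word rather
        than a single distractor character.  The half-open interval
        ``(0, 1]`` is accepted; 1 yields a stream of back-to-back chunks.
        The default 0.2 keeps the stream mostly background (roughly half
        the time in chunks of length 4, with ~80% of chunk presentations
        preceded by a distractor) while still providing a couple dozen
        presentations per 10 s stream.
    total_duration
        Stream length in ms.  The number of character epochs is
        ``total_duration // char_duration``.
    """

    alphabet_size: int = 10
    chunk: tuple[int, ...] = (0, 1, 2, 3)
    char_duration: float = 50.0
    chunk_rate: float = 0.2
    total_duration: float = 10_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chunk", tuple(int(c) for c in self.chunk))
        if len(self.chunk) < 2:
            raise ProtocolError("chunk must contain at least 2 characters")
        if len(set(self.chunk)) != len(self.chunk):
            raise ProtocolError("chunk characters must be distinct")
        if any(c < 0 or c >= self.alphabet_size for c in self.chunk):
            raise ProtocolError("chunk characters must be alphabet members")
        if self.alphabet_size <= len(self.chunk):
            raise ProtocolError(
                "alphabet must be larger than the chunk: no distractor "
                "characters are available"
            )
        if not (0.0 < self.chunk_rate <= 1.0):
            raise ProtocolError("chunk_rate must lie in (0, 1]")
        if self.char_duration < 1.0:
            raise ProtocolError("char_duration must be at least 1 ms")
        if self.total_duration < self.char_duration:
            raise ProtocolError("total_duration shorter than one epoch")

    @property
    def chunk_length(self) -> int:
        return len(self.chunk)

    @property
    def window_length(self) -> float:
        """Duration of one full chunk presentation, in ms."""
        return self.chunk_length * self.char_duration

    @property
    def n_epochs(self) -> int:
        return int(self.total_duration // self.char_duration)

    @property
    def distractors(self) -> tuple[int, ...]:
        return tuple(c for c in range(self.alphabet_size) if c not in self.chunk)


@dataclass(frozen=True)
class InputSignal:
    """A time-resolved one-hot input stream with chunk annotations.

    Attributes
    ----------
    currents
        ``(n_steps, alphabet_size)`` matrix; each row has exactly one
        entry equal to 1.
    windows
        Sorted, disjoint half-open intervals ``[start_ms, end_ms)``
        covering each full chunk presentation.
    character_log
        Emitted character per epoch.
    step_characters
        Emitted character per timestep (``character_log`` upsampled).
    """

    currents: np.ndarray
    windows: tuple[tuple[float, float], ...]
    character_log: np.ndarray
    step_characters: np.ndarray
    dt: float
    char_duration: float

    @property
    def n_steps(self) -> int:
        return self.currents.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.currents.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def truncated(self, n_steps: int) -> "InputSignal":
        """Return the first ``n_steps`` timesteps as a new signal."""
        t_end = n_steps * self.dt
        windows = tuple(w for w in self.windows if w[1] <= t_end)
        n_epochs = int(n_steps * self.dt // self.char_duration)
        return InputSignal(
            currents=self.currents[:n_steps],
            windows=windows,
            character_log=self.character_log[:n_epochs],
            step_characters=self.step_characters[:n_steps],
            dt=self.dt,
            char_duration=self.char_duration,
        )


def generate_sequence(
    protocol: ChunkProtocol, seed: int | np.random.SeedSequence
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Draw a character stream with embedded chunk words.

    Each emission is, with probability ``chunk_rate``, the full chunk
    word, and otherwise a single uniformly drawn distractor character.
    When fewer epochs remain than the chunk length, only distractors are
    emitted (a chunk no longer fits), so the log always has exactly
    ``protocol.n_epochs`` epochs.

    Returns
    -------
    character_log : ndarray of int
        One character index per epoch.
    windows : list of (start_ms, end_ms)
        One half-open interval per chunk emission, sorted and disjoint,
        each of length ``protocol.window_length``.
    """
    rng = np.random.default_rng(seed)
    n = protocol.n_epochs
    L = protocol.chunk_length
    cd = protocol.char_duration
    chunk = np.asarray(protocol.chunk, dtype=np.int64)
    distractors = np.asarray(protocol.distractors, dtype=np.int64)

    chars = np.empty(n, dtype=np.int64)
    windows: list[tuple[float, float]] = []
    epoch = 0
    while epoch < n:
        if n - epoch >= L and rng.random() < protocol.chunk_rate:
            chars[epoch : epoch + L] = chunk
            windows.append((epoch * cd, (epoch + L) * cd))
            epoch += L
        else:
            chars[epoch] = distractors[rng.integers(len(distractors))]
            epoch += 1
    return chars, windows


def find_chunk_windows(
    character_log: Sequence[int],
    chunk: Sequence[int],
    char_duration: float,
) -> list[tuple[float, float]]:
    """Locate chunk presentations in a character log by greedy scan.

    Because distractors never use chunk characters and emissions are
    epoch-serial, a greedy left-to-right non-overlapping scan recovers
    exactly the emitted windows.
    """
    chars = np.asarray(character_log)
    word = np.asarray(chunk)
    L = len(word)
    windows = []
    i = 0
    while i + L <= len(chars):
        if np.array_equal(chars[i : i + L], word):
            windows.append((i * char_duration, (i + L) * char_duration))
            i += L
        else:
            i += 1
    return windows


def encode_one_hot(
    character_log: Sequence[int],
    protocol: ChunkProtocol,
    timestep: float,
    windows: Sequence[tuple[float, float]] | None = None,
) -> InputSignal:
    """Expand a character log into one-hot input currents.

    ``timestep`` must divide ``char_duration``.  If ``windows`` is not
    supplied, chunk windows are recovered from the log by greedy scan.
    """
    steps_per_epoch = protocol.char_duration / timestep
    if abs(steps_per_epoch - round(steps_per_epoch)) > 1e-9:
        raise EncodingError(
            f"timestep {timestep} ms does not divide "
            f"char_duration {protocol.char_duration} ms"
        )
    spe = int(round(steps_per_epoch))
    chars = np.asarray(character_log, dtype=np.int64)
    if chars.size and (chars.min() < 0 or chars.max() >= protocol.alphabet_size):
        raise EncodingError("character log contains symbols outside the alphabet")

    step_chars = np.repeat(chars, spe)
    n_steps = step_chars.size
    currents = np.zeros((n_steps, protocol.alphabet_size))
    if n_steps:
        currents[np.arange(n_steps), step_chars] = 1.0
    if windows is None:
        windows = find_chunk_windows(chars, protocol.chunk, protocol.char_duration)
    return InputSignal(
        currents=currents,
        windows=tuple((float(a), float(b)) for a, b in windows),
        character_log=chars,
        step_characters=step_chars,
        dt=float(timestep),
        char_duration=protocol.char_duration,
    )


def generate_input(
    protocol: ChunkProtocol,
    seed: int | np.random.SeedSequence,
    timestep: float = 1.0,
) -> InputSignal:
    """Draw a stream and encode it in one call."""
    chars, windows = generate_sequence(protocol, seed)
    return encode_one_hot(chars, protocol, timestep, windows=windows)


def write_stream(character_log: Sequence[int], path: str | Path) -> None:
    """Export the character stream as one symbol index per line."""
    Path(path).write_text("\n".join(str(int(c)) for c in character_log) + "\n")


def write_windows(windows: Sequence[tuple[float, float]], path: str | Path) -> None:
    """Export chunk windows as a 2-column CSV (start_ms,end_ms)."""
    lines = ["start_ms,end_ms"]
    lines += [f"{a:g},{b:g}" for a, b in windows]
    Path(path).write_text("\n".join(lines) + "\n")
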