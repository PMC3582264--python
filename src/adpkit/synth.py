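"""Seeded synthetic data: sequences, mutated pairs, and noisy flowgram pairs.

All generators are pure functions of their seed (numpy ``Generator``
underneath), so fixtures are reproducible and never stored on disk.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .errors import InputFormatError
from .io import FlowgramRecord

#: Nucleotide flow order of one pyrosequencing cycle.
FLOW_ORDER = "TACG"
_CHANNEL = {c: i for i, c in enumerate(FLOW_ORDER)}


def generate_sequence(alphabet: str, length: int, seed: Optional[int] = None) -> str:
    """A uniform random sequence over ``alphabet`` of the given length."""
    if length < 0:
        raise InputFormatError("length must be >= 0")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


def generate_pair(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    seed: Optional[int] = None,
    alphabet: str = "ACGT",
) -> Tuple[str, str]:
    """The sequence and a mutated copy with the given per-position rates.

    Substitutions replace a position with a different character; indels
    split the rate evenly between deleting the position and inserting a
    random character before it.
    """
    for r in (sub_rate, indel_rate):
        if not 0.0 <= r <= 1.0:
            raise InputFormatError("mutation rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    out = []
    for c in seq:
        if rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(rng.choice(letters)))  # insertion before c
        if rng.random() < sub_rate:
            others = [x for x in letters if x != c]
            out.append(str(rng.choice(others)) if others else c)
        else:
            out.append(c)
    return seq, "".join(out)


def ideal_flowgram(seq: str, record_id: str = "ideal") -> FlowgramRecord:
    """The noise-free flowgram of a nucleotide sequence.

    Each homopolymer run emits one frame of four flows (order T, A, C, G)
    carrying the run length in the run nucleotide's channel and zero
    elsewhere.
    """
    flows = []
    i = 0
    while i < len(seq):
        c = seq[i]
        if c not in _CHANNEL:
            raise InputFormatError(f"non-nucleotide character {c!r} in sequence")
        j = i
        while j < len(seq) and seq[j] == c:
            j += 1
        frame = [0.0, 0.0, 0.0, 0.0]
        frame[_CHANNEL[c]] = float(j - i)
        flows.extend(frame)
        i = j
    return FlowgramRecord(record_id, tuple(flows))


def generate_flowgram_pair(
    seq: str,
    noise_sigma: float,
    frame_indel_prob: float,
    seed: Optional[int] = None,
) -> Tuple[FlowgramRecord, FlowgramRecord]:
    """An ideal flowgram of ``seq`` and a noisy copy.

    Noise model: additive zero-mean Gaussian noise with standard deviation
    ``noise_sigma`` on every flow value, clipped at zero, plus whole-frame
    insertions and deletions each occurring with probability
    ``frame_indel_prob`` per frame — the error modes pyrosequencing
    denoising has to absorb.
    """
    if noise_sigma < 0:
        raise InputFormatError("noise_sigma must be >= 0")
    if not 0.0 <= frame_indel_prob <= 1.0:
        raise InputFormatError("frame_indel_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    clean = ideal_flowgram(seq, record_id="clean")
    frames = [list(clean.flows[i : i + 4]) for i in range(0, len(clean.flows), 4)]
    noisy_frames = []
    for frame in frames:
        if rng.random() < frame_indel_prob:
            continue  # frame deletion
        if rng.random() < frame_indel_prob:
            spur = [abs(float(x)) for x in rng.normal(0.0, max(noise_sigma, 0.25), 4)]
            noisy_frames.append(spur)  # spurious frame insertion
        noisy_frames.append(frame)
    if not noisy_frames:
        noisy_frames = [[0.0, 0.0, 0.0, 0.0]]
    flows = []
    for frame in noisy_frames:
        for x in frame:
            v = x + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
            flows.append(max(v, 0.0))
    return clean, FlowgramRecord("noisy", tuple(flows))
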