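"""File formats: FASTA, the flowgram text format, score tables, run config.

FASTA goes through Biopython.  Flowgrams use a plain-text, FASTA-like
format of this package's own (binary SFF is out of scope): a ``>id`` header
followed by whitespace-separated non-negative floats, four per frame::

    >read1
    1.02 0.10 2.90 0.00
    0.98 0.05 0.02 1.10
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import yaml
from Bio import SeqIO

from .errors import InputFormatError


@dataclass(frozen=True)
class FlowgramRecord:
    """One flowgram: an id and a flat sequence of flow values, 4 per frame."""

    id: str
    flows: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.flows) % 4 != 0:
            raise InputFormatError(
                f"flowgram {self.id!r}: {len(self.flows)} flow values is not a "
                f"multiple of 4"
            )
        for v in self.flows:
            if not (v >= 0.0 and v == v and v != float("inf")):
                raise InputFormatError(
                    f"flowgram {self.id!r}: flow value {v!r} is not finite and >= 0"
                )

    @property
    def frames(self) -> List[Tuple[float, ...]]:
        return [tuple(self.flows[i : i + 4]) for i in range(0, len(self.flows), 4)]

    def __len__(self) -> int:
        return len(self.flows)


def read_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) in file order.

    U and T are preserved as read (merely uppercased).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise InputFormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise InputFormatError(f"{path}: malformed FASTA (no '>' header)")
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputFormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path: Union[str, Path], records: Sequence[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_flowgrams(path: Union[str, Path]) -> List[FlowgramRecord]:
    """Read the flowgram text format; validates frame width and value range."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise InputFormatError(f"{path}: empty flowgram file")
    records: List[FlowgramRecord] = []
    rid: Optional[str] = None
    values: List[float] = []

    def flush() -> None:
        nonlocal rid, values
        if rid is None:
            return
        try:
            records.append(FlowgramRecord(rid, tuple(values)))
        except InputFormatError as exc:
            raise InputFormatError(f"{path}: {exc}") from None
        rid, values = None, []

    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rid = line[1:].split()[0] if line[1:].strip() else ""
            if not rid:
                raise InputFormatError(f"{path}:{lineno}: empty flowgram header")
        else:
            if rid is None:
                raise InputFormatError(f"{path}:{lineno}: flow values before any header")
            for tok in line.split():
                try:
                    v = float(tok)
                except ValueError:
                    raise InputFormatError(
                        f"{path}:{lineno}: not a flow value: {tok!r}"
                    ) from None
                if v < 0:
                    raise InputFormatError(
                        f"{path}:{lineno}: negative flow value {v} in record {rid!r}"
                    )
                values.append(v)
    flush()
    if not records:
        raise InputFormatError(f"{path}: no flowgram records")
    return records


def write_flowgrams(path: Union[str, Path], records: Sequence[FlowgramRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for frame in rec.frames:
                fh.write(" ".join(f"{v:g}" for v in frame) + "\n")


def read_score_table(path: Union[str, Path]) -> Callable[[float, float], float]:
    """Read a mismatch score table from TSV: columns ``a  b  score``.

    Keys are matched on rounded flow values, symmetrically.  A missing pair
    raises at lookup time.
    """
    from .applications import iround

    table: Dict[Tuple[int, int], float] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise InputFormatError(
                f"{path}:{lineno}: expected 3 columns (a, b, score), got {len(parts)}"
            )
        try:
            a, b, s = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError:
            raise InputFormatError(f"{path}:{lineno}: non-numeric entry") from None
        key = (iround(a), iround(b))
        table[key] = s
        table[(key[1], key[0])] = s

    def lookup(a: float, b: float) -> float:
        key = (iround(a), iround(b))
        if key not in table:
            raise InputFormatError(f"score table has no entry for flow pair {key}")
        return table[key]

    return lookup


@dataclass
class RunConfig:
    """Key-value run configuration, loadable from YAML."""

    app: Optional[str] = None
    instance: Optional[str] = None
    table_mode: str = "auto"
    band: Optional[int] = None
    k: int = 1
    seed: Optional[int] = None
    co_optimal: bool = True
    output: str = "text"
    pairs: Optional[str] = None
    extra: Dict = field(default_factory=dict)


def load_config(path: Union[str, Path]) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise InputFormatError(f"{path}: invalid YAML: {exc}") from None
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise InputFormatError(f"{path}: config must be a mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if hasattr(cfg, key) and key != "extra":
            setattr(cfg, key, value)
        else:
            cfg.extra[key] = value
    return cfg
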