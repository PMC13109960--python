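"""Arithmetic stimulus generation.

Enumerates single/double-digit addition and subtraction problems whose results
lie in 0..18 (380 problems for the default task: 190 additions, 190
subtractions, exactly 20 problems per result), synthesizes digit and operator
glyphs procedurally (handwritten-style stroke rendering or a printed bitmap
font), and renders each problem as a five-slot ``3 x 28 x 140`` image laid out
as ``T1 U1 S T2 U2`` (tens digit, unit digit, operator symbol, tens digit,
unit digit).  Single-digit operands receive an all-black glyph in their tens
slot.  The operator glyphs are built from a "1"-like vertical stroke and its
rotation, mirroring how one would improvise them from a handwritten-digit
corpus that contains no symbols.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
from scipy import ndimage

ADD = "addition"
SUB = "subtraction"
OPERATIONS = (ADD, SUB)

GLYPH_SIZE = 28
SLOTS = 5
IMAGE_SHAPE = (3, GLYPH_SIZE, GLYPH_SIZE * SLOTS)

DIGIT_CHARS = tuple(str(d) for d in range(10))
CHARSET = DIGIT_CHARS + ("plus", "minus", "blank")

STYLES = ("handwritten_synthetic", "printed", "mixed")


# ---------------------------------------------------------------------------
# Problem enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ProblemSpec:
    """One arithmetic problem: ``operand1 (op) operand2 = result``."""

    operand1: int
    operand2: int
    operation: str

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise ValueError(f"unknown operation {self.operation!r}")
        if self.operand1 < 0 or self.operand2 < 0:
            raise ValueError("operands must be non-negative")

    @property
    def result(self) -> int:
        if self.operation == ADD:
            return self.operand1 + self.operand2
        return self.operand1 - self.operand2

    def __str__(self) -> str:  # e.g. "10-2"
        sym = "+" if self.operation == ADD else "-"
        return f"{self.operand1}{sym}{self.operand2}"


def enumerate_problems(
    result_min: int = 0,
    result_max: int = 18,
    operations: Iterable[str] = OPERATIONS,
) -> list[ProblemSpec]:
    """Enumerate all problems with results in ``[result_min, result_max]``.

    Ordered operand pairs ``(a, b)`` of non-negative integers are included
    when ``a (op) b`` lands in the result range; operands never exceed
    ``result_max``.  For the default task this yields 380 distinct problems,
    20 per result value.  The returned order is canonical: additions before
    subtractions, then ascending result, then ascending first operand.
    """
    ops = tuple(operations)
    if not ops:
        raise ValueError("operations must be a non-empty set")
    for op in ops:
        if op not in OPERATIONS:
            raise ValueError(f"unknown operation {op!r}")
    if not (0 <= result_min <= result_max):
        raise ValueError("require 0 <= result_min <= result_max")

    problems: list[ProblemSpec] = []
    for op in (ADD, SUB):
        if op not in ops:
            continue
        for s in range(result_min, result_max + 1):
            if op == ADD:
                pairs = [(a, s - a) for a in range(0, s + 1)]
            else:
                pairs = [(a, a - s) for a in range(s, result_max + 1)]
            problems.extend(ProblemSpec(a, b, op) for a, b in pairs)
    return problems


def problem_order_key(spec: ProblemSpec) -> tuple:
    """Canonical sort key: additions first, then result, then first operand."""
    return (0 if spec.operation == ADD else 1, spec.result, spec.operand1)


# ---------------------------------------------------------------------------
# Glyph synthesis
# ---------------------------------------------------------------------------

# Digit skeletons as polylines in a unit box (x right, y down).  Arcs are
# expressed with the helper below; coordinates were tuned by eye for legibility
# at 28 x 28 after stroke rendering.

def _arc(cx: float, cy: float, rx: float, ry: float,
         deg0: float, deg1: float, n: int = 24) -> list[tuple[float, float]]:
    t = np.radians(np.linspace(deg0, deg1, n))
    return list(zip(cx + rx * np.cos(t), cy - ry * np.sin(t)))


_DIGIT_STROKES: dict[str, list[list[tuple[float, float]]]] = {
    "0": [_arc(0.5, 0.5, 0.23, 0.34, 90, 450)],
    "1": [[(0.36, 0.28), (0.54, 0.12), (0.54, 0.88)]],
    "2": [_arc(0.5, 0.28, 0.2, 0.17, 160, -10)
          + [(0.66, 0.4), (0.3, 0.85), (0.74, 0.85)]],
    "3": [_arc(0.47, 0.3, 0.2, 0.17, 150, -70),
          _arc(0.47, 0.66, 0.23, 0.2, 80, -140)],
    "4": [[(0.64, 0.12), (0.28, 0.58), (0.76, 0.58)],
          [(0.64, 0.34), (0.64, 0.9)]],
    "5": [[(0.72, 0.12), (0.36, 0.12), (0.33, 0.46)],
          _arc(0.49, 0.65, 0.23, 0.21, 115, -130)],
    "6": [[(0.62, 0.1)] + _arc(0.68, 0.52, 0.45, 0.42, 130, 180)
          + _arc(0.47, 0.65, 0.2, 0.2, 180, -180)],
    "7": [[(0.28, 0.13), (0.74, 0.13), (0.44, 0.88)]],
    "8": [_arc(0.5, 0.3, 0.17, 0.17, 90, 450),
          _arc(0.5, 0.67, 0.21, 0.2, 90, -270)],
    "9": [_arc(0.5, 0.34, 0.19, 0.2, 0, 360),
          [(0.69, 0.38), (0.66, 0.6), (0.56, 0.88)]],
}

# 5x7 printed bitmap font (1 = ink); a deliberately plain fixed-width face.
_PRINTED_FONT = {
    "0": ["01110", "10001", "10011", "10101", "11001", "10001", "01110"],
    "1": ["00100", "01100", "00100", "00100", "00100", "00100", "01110"],
    "2": ["01110", "10001", "00001", "00110", "01000", "10000", "11111"],
    "3": ["11110", "00001", "00001", "01110", "00001", "00001", "11110"],
    "4": ["00010", "00110", "01010", "10010", "11111", "00010", "00010"],
    "5": ["11111", "10000", "11110", "00001", "00001", "10001", "01110"],
    "6": ["00110", "01000", "10000", "11110", "10001", "10001", "01110"],
    "7": ["11111", "00001", "00010", "00100", "01000", "01000", "01000"],
    "8": ["01110", "10001", "10001", "01110", "10001", "10001", "01110"],
    "9": ["01110", "10001", "10001", "01111", "00001", "00010", "01100"],
    "plus": ["00000", "00100", "00100", "11111", "00100", "00100", "00000"],
    "minus": ["00000", "00000", "00000", "11111", "00000", "00000", "00000"],
}


def _render_strokes(strokes: Sequence[Sequence[tuple[float, float]]],
                    thickness: float, blur: float) -> np.ndarray:
    """Rasterize unit-box polylines into a 28x28 intensity array in [0, 1]."""
    box, off = 22.0, 3.0
    pts: list[np.ndarray] = []
    for line in strokes:
        p = np.asarray(line, dtype=np.float64) * box + off
        # resample at ~0.7 px spacing so disks overlap into smooth strokes
        for a, b in zip(p[:-1], p[1:]):
            seg = np.linalg.norm(b - a)
            n = max(int(seg / 0.7) + 1, 2)
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts.append(a + t * (b - a))
    path = np.concatenate(pts, axis=0)
    yy, xx = np.mgrid[0:GLYPH_SIZE, 0:GLYPH_SIZE]
    d2 = ((xx[..., None] - path[:, 0]) ** 2
          + (yy[..., None] - path[:, 1]) ** 2)
    canvas = np.exp(-d2.min(axis=-1) / (2.0 * (thickness / 2.0) ** 2))
    if blur > 0:
        canvas = ndimage.gaussian_filter(canvas, blur)
    canvas = np.clip(canvas * 1.6, 0.0, 1.0)
    return canvas.astype(np.float32)


#: Strength of the handwritten deformation.  The default keeps every glyph
#: class clearly legible while still varying stroke geometry per variant.
DEFAULT_JITTER = 0.5


def _jitter_strokes(strokes, rng: np.random.Generator,
                    j: float = DEFAULT_JITTER):
    """Random per-variant deformation: point noise, rotation, scale, shift."""
    ang = rng.normal(0.0, np.radians(5.0) * j)
    sc = rng.uniform(1.0 - 0.12 * j, 1.0 + 0.12 * j)
    shear = rng.normal(0.0, 0.08 * j)
    dx, dy = rng.normal(0.0, 0.035 * j, size=2)
    ca, sa = np.cos(ang), np.sin(ang)
    out = []
    for line in strokes:
        p = np.asarray(line, dtype=np.float64)
        p = p + rng.normal(0.0, 0.018 * j, size=p.shape)
        c = p - 0.5
        c = np.stack([ca * c[:, 0] - sa * c[:, 1] + shear * c[:, 1],
                      sa * c[:, 0] + ca * c[:, 1]], axis=1)
        out.append((c * sc + 0.5 + [dx, dy]).tolist())
    return out


def _vertical_stroke(length_px: float, thickness: float,
                     jitter_rng: np.random.Generator | None,
                     jitter: float = DEFAULT_JITTER) -> np.ndarray:
    """Centered vertical bar, the "1"-like stroke primitive for operators."""
    half = length_px / (2.0 * 22.0)
    line = [[(0.5, 0.5 - half), (0.5, 0.5 + half)]]
    blur = 0.4
    if jitter_rng is not None:
        line = _jitter_strokes(line, jitter_rng, jitter)
        blur = abs(jitter_rng.normal(0.4, 0.15))
    return _render_strokes(line, thickness, blur)


def _printed_glyph(char: str, rng: np.random.Generator) -> np.ndarray:
    bitmap = np.array([[int(c) for c in row] for row in _PRINTED_FONT[char]],
                      dtype=np.float32)
    big = np.kron(bitmap, np.ones((3, 3), dtype=np.float32))  # 15 x 21
    canvas = np.zeros((GLYPH_SIZE, GLYPH_SIZE), dtype=np.float32)
    dy = (GLYPH_SIZE - big.shape[0]) // 2 + int(rng.integers(-2, 3))
    dx = (GLYPH_SIZE - big.shape[1]) // 2 + int(rng.integers(-2, 3))
    canvas[dy:dy + big.shape[0], dx:dx + big.shape[1]] = big
    return np.clip(ndimage.gaussian_filter(canvas, 0.5) * 1.5, 0, 1)


@dataclass
class GlyphBank:
    """Bank of rendered glyph variants, ``char -> (n, 3, 28, 28)`` in [0, 1]."""

    style: str
    rng_seed: int
    glyphs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return next(iter(self.glyphs.values())).shape[0]


def _handwritten_variant(char: str, rng: np.random.Generator,
                         jitter: float = DEFAULT_JITTER) -> np.ndarray:
    thickness = float(np.clip(rng.normal(2.1, 0.5), 1.3, 3.4))
    if char in _DIGIT_STROKES:
        strokes = _jitter_strokes(_DIGIT_STROKES[char], rng, jitter)
        blur = abs(rng.normal(0.4, 0.15))
        return _render_strokes(strokes, thickness, blur)
    # operators: vertical "1"-like stroke, rotated for the horizontal bar
    length = float(np.clip(rng.normal(16.0, 2.0), 10.0, 21.0))
    if char == "minus":
        return np.ascontiguousarray(
            np.rot90(_vertical_stroke(length, thickness, rng, jitter)))
    if char == "plus":
        vert = _vertical_stroke(length, thickness, rng, jitter)
        horiz = np.rot90(_vertical_stroke(length, thickness, rng, jitter))
        return np.maximum(vert, horiz)
    raise ValueError(f"unknown character {char!r}")


def build_glyph_bank(style: str = "handwritten_synthetic",
                     n_variants: int = 100,
                     rng_seed: int = 0,
                     jitter: float = DEFAULT_JITTER) -> GlyphBank:
    """Render ``n_variants`` glyphs per character in the requested style.

    ``handwritten_synthetic`` draws jittered stroke paths; ``printed`` stamps a
    fixed bitmap font with small translations; ``mixed`` draws each variant
    from one of the two styles at random.  Deterministic given the seed.
    """
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {STYLES}")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(rng_seed)
    glyphs: dict[str, np.ndarray] = {}
    for char in CHARSET:
        if char == "blank":
            glyphs[char] = np.zeros((n_variants, 3, GLYPH_SIZE, GLYPH_SIZE),
                                    dtype=np.float32)
            continue
        variants = np.empty((n_variants, GLYPH_SIZE, GLYPH_SIZE),
                            dtype=np.float32)
        for i in range(n_variants):
            if style == "printed" or (style == "mixed" and rng.random() < 0.5):
                variants[i] = _printed_glyph(char, rng)
            else:
                variants[i] = _handwritten_variant(char, rng, jitter)
        glyphs[char] = np.repeat(variants[:, None], 3, axis=1)
    return GlyphBank(style=style, rng_seed=rng_seed, glyphs=glyphs)


# ---------------------------------------------------------------------------
# Problem rendering and dataset assembly
# ---------------------------------------------------------------------------

def problem_characters(spec: ProblemSpec) -> list[str]:
    """Five slot characters ``[T1, U1, S, T2, U2]`` for a problem."""
    if spec.operand1 >= 100 or spec.operand2 >= 100:
        raise ValueError(f"operand >= 100 unsupported in 5-slot layout: {spec}")
    sym = "plus" if spec.operation == ADD else "minus"

    def digits(n: int) -> tuple[str, str]:
        return ("blank" if n < 10 else str(n // 10), str(n % 10))

    t1, u1 = digits(spec.operand1)
    t2, u2 = digits(spec.operand2)
    return [t1, u1, sym, t2, u2]


def render_problem(spec: ProblemSpec, bank: GlyphBank,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one problem variant as a ``3 x 28 x 140`` image in [0, 1]."""
    chars = problem_characters(spec)
    image = np.empty(IMAGE_SHAPE, dtype=np.float32)
    for slot, char in enumerate(chars):
        pool = bank.glyphs[char]
        idx = int(rng.integers(pool.shape[0]))
        image[:, :, slot * GLYPH_SIZE:(slot + 1) * GLYPH_SIZE] = pool[idx]
    return image


@dataclass
class StimulusDataset:
    """Rendered problem variants with a disjoint train/test split.

    Images are stored as uint8 (0..255) to keep the full-scale dataset within
    memory; ``images_float`` converts batches back to [0, 1] float32.
    """

    images: np.ndarray          # (n, 3, 28, 140) uint8
    labels: np.ndarray          # (n,) result value 0..18
    problem_ids: np.ndarray     # (n,) index into `problems`
    is_train: np.ndarray        # (n,) bool
    problems: list[ProblemSpec]
    variants_per_problem: int
    rng_seed: int
    style: str

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_train)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_train)

    def images_float(self, indices: np.ndarray) -> np.ndarray:
        return self.images[indices].astype(np.float32) / 255.0

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("problem_ids", data=self.problem_ids)
            f.create_dataset("is_train", data=self.is_train)
            f.attrs["manifest"] = json.dumps({
                "variants_per_problem": self.variants_per_problem,
                "rng_seed": self.rng_seed,
                "style": self.style,
                "problems": [[p.operand1, p.operand2, p.operation]
                             for p in self.problems],
            })

    @classmethod
    def load(cls, path: str) -> "StimulusDataset":
        with h5py.File(path, "r") as f:
            manifest = json.loads(f.attrs["manifest"])
            return cls(
                images=f["images"][...],
                labels=f["labels"][...],
                problem_ids=f["problem_ids"][...],
                is_train=f["is_train"][...],
                problems=[ProblemSpec(a, b, op)
                          for a, b, op in manifest["problems"]],
                variants_per_problem=manifest["variants_per_problem"],
                rng_seed=manifest["rng_seed"],
                style=manifest["style"],
            )


def _image_digest(image_u8: np.ndarray) -> str:
    return hashlib.sha1(image_u8.tobytes()).hexdigest()


def build_dataset(problems: Sequence[ProblemSpec], bank: GlyphBank,
                  variants_per_problem: int = 100,
                  rng_seed: int = 0) -> StimulusDataset:
    """Render a balanced dataset with half the variants held out for testing.

    Each problem contributes ``variants_per_problem`` independent renders,
    split half/half into train and test by a seeded random assignment.  Since
    the enumeration is balanced (20 problems per result for the default task),
    per-result counts are equal within each split.  Duplicate renders across
    the split boundary are re-drawn so train and test variants are disjoint.
    """
    if variants_per_problem % 2 != 0 or variants_per_problem < 2:
        raise ValueError("variants_per_problem must be even and >= 2")
    problems = sorted(problems, key=problem_order_key)
    rng = np.random.default_rng(rng_seed)
    n_total = len(problems) * variants_per_problem
    images = np.empty((n_total,) + IMAGE_SHAPE, dtype=np.uint8)
    labels = np.empty(n_total, dtype=np.int64)
    problem_ids = np.empty(n_total, dtype=np.int64)
    is_train = np.zeros(n_total, dtype=bool)

    i = 0
    for pid, spec in enumerate(problems):
        seen: set[str] = set()
        for _ in range(variants_per_problem):
            for _attempt in range(32):
                img = np.round(render_problem(spec, bank, rng) * 255)
                img = img.astype(np.uint8)
                digest = _image_digest(img)
                if digest not in seen:
                    seen.add(digest)
                    break
            images[i] = img
            labels[i] = spec.result
            problem_ids[i] = pid
            i += 1
        rows = np.arange(i - variants_per_problem, i)
        train_rows = rng.permutation(rows)[: variants_per_problem // 2]
        is_train[train_rows] = True

    return StimulusDataset(images=images, labels=labels,
                           problem_ids=problem_ids, is_train=is_train,
                           problems=list(problems),
                           variants_per_problem=variants_per_problem,
                           rng_seed=rng_seed, style=bank.style)
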