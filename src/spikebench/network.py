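"""Seeded connectivity builders and edge-list serialization.

Two wiring schemes are used by the benchmark networks: Bernoulli random
digraphs (every ordered pair connected independently with probability p)
and fixed-out-degree graphs (every source picks k distinct random targets
without replacement).  Autapses and duplicate (pre, post) pairs are never
generated.  Generation order is fixed (row-major over presynaptic index,
one uniform draw per candidate pair / one choice call per source) so a
given seed always reproduces the same edge list byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EdgeList",
    "ConnectivityConfig",
    "connect_bernoulli",
    "connect_fixed_outdegree",
    "write_edges",
    "read_edges",
]

# rows generated per RNG call when sampling Bernoulli blocks; chosen to cap
# the temporary uniform matrix at a few MB.  Does not affect the stream:
# draws are consumed in row-major order regardless of block size.
_BLOCK_ROWS = 256


@dataclass
class EdgeList:
    """Directed weighted edges between two (possibly identical) populations.

    pre/post are local 0-based ids; weight is mV (delta synapses) or nS
    (conductance synapses); delay in ms.
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    n_pre: int
    n_post: int

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        self.delay = np.asarray(self.delay, dtype=float)
        if not (len(self.pre) == len(self.post) == len(self.weight) == len(self.delay)):
            raise ValueError("edge columns must have equal length")

    def __len__(self) -> int:
        return len(self.pre)

    def validate(self, same_population: bool = False) -> None:
        """Check id ranges, absence of duplicates and (optionally) autapses."""
        if len(self) == 0:
            return
        if self.pre.min() < 0 or self.pre.max() >= self.n_pre:
            raise ValueError("presynaptic id out of range")
        if self.post.min() < 0 or self.post.max() >= self.n_post:
            raise ValueError("postsynaptic id out of range")
        pairs = self.pre * self.n_post + self.post
        if len(np.unique(pairs)) != len(pairs):
            raise ValueError("duplicate (pre, post) pair")
        if same_population and np.any(self.pre == self.post):
            raise ValueError("autapse present")

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre, minlength=self.n_pre)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.post, minlength=self.n_post)


@dataclass(frozen=True)
class ConnectivityConfig:
    """Connection probabilities / out-degree of the two benchmark networks."""

    p_ee: float = 0.005
    p_ei: float = 0.3
    p_ii: float = 0.3
    p_ie: float = 0.2
    p_se: float = 0.15
    out_degree: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ee", "p_ei", "p_ii", "p_ie", "p_se"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def connect_bernoulli(
    n_pre: int,
    n_post: int,
    p: float,
    seed,
    same_population: bool = False,
    weight: float = 0.0,
    delay: float = 0.0,
) -> EdgeList:
    """Bernoulli(p) digraph: each ordered pair independently with prob p.

    ``same_population`` marks pre and post as the same population, in which
    case self-edges (i, i) are excluded.  ``seed`` may be an int, a
    SeedSequence or an existing Generator.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability must be in [0, 1], got {p}")
    if same_population and n_pre != n_post:
        raise ValueError("same_population requires n_pre == n_post")
    rng = _as_rng(seed)
    pres, posts = [], []
    for start in range(0, n_pre, _BLOCK_ROWS):
        stop = min(start + _BLOCK_ROWS, n_pre)
        u = rng.random((stop - start, n_post))
        mask = u < p
        if same_population:
            rows = np.arange(start, stop)
            mask[np.arange(stop - start), rows] = False
        i, j = np.nonzero(mask)
        pres.append(i + start)
        posts.append(j)
    pre = np.concatenate(pres) if pres else np.empty(0, dtype=np.int64)
    post = np.concatenate(posts) if posts else np.empty(0, dtype=np.int64)
    n = len(pre)
    return EdgeList(
        pre=pre,
        post=post,
        weight=np.full(n, weight),
        delay=np.full(n, delay),
        n_pre=n_pre,
        n_post=n_post,
    )


def connect_fixed_outdegree(
    n: int,
    k: int,
    seed,
    weight: float = 0.0,
    delay: float = 0.0,
) -> EdgeList:
    """Every source connects to exactly k distinct targets (no autapse).

    Targets are sampled without replacement, one ``choice`` call per source
    in ascending source order.
    """
    if k < 0:
        raise ValueError(f"out-degree must be non-negative, got {k}")
    if k >= n:
        raise ValueError(f"out-degree k={k} must be smaller than n={n}")
    rng = _as_rng(seed)
    pre = np.repeat(np.arange(n, dtype=np.int64), k)
    posts = np.empty(n * k, dtype=np.int64)
    for i in range(n):
        # sample from n-1 candidates, then shift indices >= i past the source
        t = rng.choice(n - 1, size=k, replace=False)
        t[t >= i] += 1
        posts[i * k : (i + 1) * k] = t
    return EdgeList(
        pre=pre,
        post=posts,
        weight=np.full(n * k, weight),
        delay=np.full(n * k, delay),
        n_pre=n,
        n_post=n,
    )


def write_edges(edges: EdgeList, path) -> None:
    """Write a TSV edge list with '#n_pre=' / '#n_post=' header lines.

    Weights and delays use repr-precision so a read round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"#n_pre={edges.n_pre}\n")
        fh.write(f"#n_post={edges.n_post}\n")
        for i in range(len(edges)):
            fh.write(
                f"{int(edges.pre[i])}\t{int(edges.post[i])}\t"
                f"{float(edges.weight[i])!r}\t{float(edges.delay[i])!r}\n"
            )


def read_edges(path) -> EdgeList:
    """Read an edge list written by :func:`write_edges`.

    Malformed rows (wrong column count, non-numeric fields) raise a
    ValueError naming the 1-based line number.
    """
    n_pre = n_post = None
    pre, post, weight, delay = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "n_pre":
                    n_pre = int(value)
                elif key == "n_post":
                    n_post = int(value)
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                pre.append(int(parts[0]))
                post.append(int(parts[1]))
                weight.append(float(parts[2]))
                delay.append(float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
    if n_pre is None or n_post is None:
        raise ValueError(f"{path}: missing #n_pre/#n_post header")
    return EdgeList(
        pre=np.array(pre, dtype=np.int64),
        post=np.array(post, dtype=np.int64),
        weight=np.array(weight, dtype=float),
        delay=np.array(delay, dtype=float),
        n_pre=n_pre,
        n_post=n_post,
    )
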