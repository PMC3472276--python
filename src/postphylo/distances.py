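"""Model-corrected pairwise genetic distances and a saturation diagnostic.

Distances are maximum-likelihood branch lengths between two aligned
sequences under a GTR-family substitution model, optionally with a
proportion of invariant sites (I) and discrete-gamma rate variation
(+G, 4 categories by default, median rule).  Under plain JC69 the
closed form ``d = -(3/4) ln(1 - (4/3) p)`` is used; every other
configuration goes through a 1-D likelihood optimisation over the
divergence ``t`` (expected substitutions per site, mean site rate 1).

Named model families such as TIM or TPM are expressed here as GTR with
constrained exchangeabilities — supply the six exchangeability values
directly rather than a family name.

The saturation diagnostic replaces entropy-based statistics with a
transparent ratio: per codon-position class, the mean uncorrected
p-distance over the mean corrected distance.  Multiple hits flatten p
while the corrected distance keeps growing, so the ratio drops towards
zero as a class saturates; a class is flagged when the ratio falls
below a threshold among the most divergent quartile of pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AlignedSequences",
    "SubstModel",
    "SaturatedError",
    "p_distance",
    "ml_distance",
    "combined_distance",
    "saturation_profile",
    "read_fasta",
    "write_fasta",
    "read_partition_file",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_ALPHABET = set("ACGTN-")


class SaturatedError(ValueError):
    """Observed divergence exceeds what the model can explain at any t."""


@dataclass(frozen=True)
class SubstModel:
    """GTR-family substitution model with optional I and gamma mixture.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG,
    CT, GT; ``freqs`` the stationary base frequencies (A, C, G, T).
    ``alpha`` is the gamma shape (None = no rate variation) discretised
    into ``ncat`` equal-weight categories by the median rule; ``p_inv``
    is the proportion of invariant sites folded in as a zero-rate
    category.  Site rates are normalised to mean 1, so branch lengths
    are expected substitutions per site.
    """

    family: str = "GTR"
    rates: tuple[float, ...] = (1.0,) * 6
    freqs: tuple[float, ...] = (0.25,) * 4
    p_inv: float = 0.0
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self):
        if len(self.rates) != 6 or any(r <= 0 for r in self.rates):
            raise ValueError("need 6 positive exchangeabilities (AC AG AT CG CT GT)")
        if len(self.freqs) != 4 or abs(sum(self.freqs) - 1.0) > 1e-9 or min(self.freqs) <= 0:
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError(f"p_inv must be in [0, 1), got {self.p_inv}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"gamma shape must be positive, got {self.alpha}")

    # -- constructors ---------------------------------------------------
    @classmethod
    def jc69(cls, p_inv: float = 0.0, alpha: float | None = None, ncat: int = 4):
        return cls("JC69", (1.0,) * 6, (0.25,) * 4, p_inv, alpha, ncat)

    @classmethod
    def k80(cls, kappa: float, **kw):
        return cls("K80", (1.0, kappa, 1.0, 1.0, kappa, 1.0), (0.25,) * 4, **kw)

    @classmethod
    def hky(cls, kappa: float, freqs: Sequence[float], **kw):
        return cls("HKY", (1.0, kappa, 1.0, 1.0, kappa, 1.0), tuple(freqs), **kw)

    @classmethod
    def gtr(cls, rates: Sequence[float], freqs: Sequence[float], **kw):
        return cls("GTR", tuple(rates), tuple(freqs), **kw)

    # -- derived quantities ---------------------------------------------
    def q_matrix(self) -> np.ndarray:
        """Rate matrix normalised to mean rate 1 at stationarity."""
        pi = np.asarray(self.freqs)
        r = self.rates
        ex = np.array(
            [[0, r[0], r[1], r[2]],
             [r[0], 0, r[3], r[4]],
             [r[1], r[3], 0, r[5]],
             [r[2], r[4], r[5], 0]], dtype=float,
        )
        Q = ex * pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the I+G site-rate mixture, mean rate 1."""
        cats: list[float] = []
        weights: list[float] = []
        if self.p_inv > 0:
            cats.append(0.0)
            weights.append(self.p_inv)
        if self.alpha is None:
            cats.append(1.0)
            weights.append(1.0 - self.p_inv)
        else:
            k = self.ncat
            mids = stats.gamma.ppf((2 * np.arange(k) + 1) / (2 * k),
                                   a=self.alpha, scale=1.0 / self.alpha)
            mids = mids / mids.mean()  # median-rule categories, renormalised
            cats.extend(mids)
            weights.extend([(1.0 - self.p_inv) / k] * k)
        rates = np.asarray(cats)
        w = np.asarray(weights)
        # rescale non-zero categories so the overall mean rate is 1
        nz = rates > 0
        rates = rates.copy()
        rates[nz] /= float((rates * w).sum())
        return rates, w

    def saturation_bound(self) -> float:
        """sup over t of the expected p-distance under this model."""
        pi = np.asarray(self.freqs)
        return (1.0 - self.p_inv) * (1.0 - float(np.dot(pi, pi)))

    def _eig(self):
        pi = np.asarray(self.freqs)
        Q = self.q_matrix()
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, U = np.linalg.eigh(0.5 * (B + B.T))
        left = U / sq[:, None] * 1.0  # D^{-1/2} U
        right = (U * sq[:, None]).T  # U^T D^{1/2}
        return lam, left, right

    def transition_matrices(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-category P(t * rate) stacked as (ncat, 4, 4), plus weights."""
        rates, w = self.rate_categories()
        lam, left, right = self._eig()
        P = np.stack([
            left @ (np.exp(lam * t * r)[:, None] * right) for r in rates
        ])
        return np.clip(P, 0.0, None), w


@dataclass
class AlignedSequences:
    """Equal-length nucleotide alignment over {A, C, G, T, N, -}.

    ``codon_positions`` optionally annotates each column with 1/2/3;
    ``partitions`` maps partition names to 1-based inclusive (start,
    end) column ranges that must be disjoint and cover the alignment.
    """

    seqs: dict[str, str]
    codon_positions: list[int] | None = None
    partitions: dict[str, tuple[int, int]] | None = None

    def __post_init__(self):
        if not self.seqs:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        (self.length,) = lengths
        cleaned = {}
        for lab, s in self.seqs.items():
            s = s.upper()
            # IUPAC ambiguity codes other than N are treated as N
            s = "".join(c if c in _ALPHABET else "N" for c in s)
            cleaned[lab] = s
        self.seqs = cleaned
        if self.codon_positions is not None:
            if len(self.codon_positions) != self.length:
                raise ValueError("codon annotation length mismatch")
            if not set(self.codon_positions) <= {1, 2, 3}:
                raise ValueError("codon positions must be 1, 2 or 3")
        if self.partitions is not None:
            covered: set[int] = set()
            for name, (start, end) in self.partitions.items():
                if not 1 <= start <= end <= self.length:
                    raise ValueError(f"partition {name!r} range out of bounds")
                cols = set(range(start, end + 1))
                if cols & covered:
                    raise ValueError(f"partition {name!r} overlaps another")
                covered |= cols
            if covered != set(range(1, self.length + 1)):
                raise ValueError("partitions must cover every column")

    @property
    def labels(self) -> list[str]:
        return list(self.seqs)

    def encoded(self, label: str) -> np.ndarray:
        return np.array([_CODE.get(c, -1) for c in self.seqs[label]], dtype=np.int8)

    def columns(self, which: Sequence[int] | None) -> "AlignedSequences":
        """Sub-alignment restricted to the given 0-based column indices."""
        if which is None:
            return self
        idx = list(which)
        seqs = {lab: "".join(s[i] for i in idx) for lab, s in self.seqs.items()}
        cp = None
        if self.codon_positions is not None:
            cp = [self.codon_positions[i] for i in idx]
        return AlignedSequences(seqs, cp, None)


# ----------------------------------------------------------------------
# distances


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a >= 0) & (b >= 0)


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatches among columns unambiguous in both."""
    xa, xb = _encode(a), _encode(b)
    if xa.size != xb.size:
        raise ValueError(f"sequences differ in length: {xa.size} vs {xb.size}")
    mask = _comparable(xa, xb)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable sites (every column has a gap or N)")
    return float((xa[mask] != xb[mask]).sum() / n)


def _pattern_counts(a: str, b: str) -> np.ndarray:
    xa, xb = _encode(a), _encode(b)
    if xa.size != xb.size:
        raise ValueError(f"sequences differ in length: {xa.size} vs {xb.size}")
    mask = _comparable(xa, xb)
    if not mask.any():
        raise ValueError("no comparable sites (every column has a gap or N)")
    counts = np.bincount(
        (xa[mask].astype(int) * 4 + xb[mask]).astype(int), minlength=16
    ).reshape(4, 4).astype(float)
    # time-reversible models make the expected joint pattern matrix
    # symmetric; averaging with the transpose leaves the likelihood
    # unchanged and makes d(a, b) == d(b, a) to the last bit
    return 0.5 * (counts + counts.T)


def _nll_factory(counts_models: list[tuple[np.ndarray, SubstModel]]):
    """Shared-t negative log-likelihood and derivative over partitions."""
    prepared = []
    for counts, model in counts_models:
        rates, w = model.rate_categories()
        lam, left, right = model._eig()
        pi = np.asarray(model.freqs)
        prepared.append((counts, rates, w, lam, left, right, pi))

    def site_probs(t):
        total = []
        for counts, rates, w, lam, left, right, pi in prepared:
            P = np.zeros((4, 4))
            dP = np.zeros((4, 4))
            for r, wc in zip(rates, w):
                core = np.exp(lam * t * r)
                M = left @ (core[:, None] * right)
                P += wc * M
                dP += wc * (left @ ((lam * r * core)[:, None] * right))
            joint = pi[:, None] * np.clip(P, 1e-300, None)
            djoint = pi[:, None] * dP
            total.append((counts, joint, djoint))
        return total

    def nll(t):
        return -sum(
            float((c * np.log(j)).sum()) for c, j, _ in site_probs(t)
        )

    def dnll(t):
        return -sum(
            float((c * dj / j).sum()) for c, j, dj in site_probs(t)
        )

    return nll, dnll


def _optimize_t(counts_models, t_hint: float) -> float:
    nll, dnll = _nll_factory(counts_models)
    hi = 40.0
    res = optimize.minimize_scalar(nll, bounds=(1e-12, hi), method="bounded",
                                   options={"xatol": 1e-14})
    t = float(res.x)
    if t > hi - 1e-3:
        raise SaturatedError(
            "saturated: the likelihood keeps increasing with t; observed "
            "divergence exceeds what the model can explain"
        )
    # Newton polish on the score function for machine-precision argmin
    for _ in range(30):
        g = dnll(t)
        h = (dnll(t + 1e-6) - dnll(t - 1e-6)) / 2e-6
        if h <= 0 or not math.isfinite(h):
            break
        step = g / h
        t_new = min(max(t - step, 1e-15), hi)
        if abs(t_new - t) <= 1e-15 * max(t, 1.0):
            t = t_new
            break
        t = t_new
    return max(t, 0.0)


def ml_distance(a: str, b: str, model: SubstModel, force_generic: bool = False) -> float:
    """ML divergence (substitutions/site) between two aligned sequences.

    Plain JC69 uses the closed form; any other configuration (or
    ``force_generic=True``) maximises the pairwise likelihood over t.
    """
    p = p_distance(a, b)
    if p == 0.0:
        return 0.0
    bound = model.saturation_bound()
    if p >= bound - 1e-12:
        raise SaturatedError(
            f"saturated: p-distance {p:.4f} >= model bound {bound:.4f}"
        )
    plain_jc = (
        model.rates == (1.0,) * 6
        and tuple(model.freqs) == (0.25,) * 4
        and model.p_inv == 0.0
        and model.alpha is None
    )
    if plain_jc and not force_generic:
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    counts = _pattern_counts(a, b)
    return _optimize_t([(counts, model)], t_hint=p)


def combined_distance(
    aln: AlignedSequences,
    models: Mapping[str, SubstModel],
    label_a: str,
    label_b: str,
) -> float:
    """Shared-branch-length ML distance over a partitioned alignment.

    Each partition keeps its own substitution model; a single
    divergence t is optimised against the summed log-likelihood.
    """
    if aln.partitions is None:
        raise ValueError("alignment carries no partition definition")
    missing = set(aln.partitions) - set(models)
    if missing:
        raise ValueError(f"no model supplied for partition(s) {sorted(missing)}")
    counts_models = []
    ps = []
    for name, (start, end) in aln.partitions.items():
        sub_a = aln.seqs[label_a][start - 1:end]
        sub_b = aln.seqs[label_b][start - 1:end]
        counts_models.append((_pattern_counts(sub_a, sub_b), models[name]))
        ps.append(p_distance(sub_a, sub_b))
    if all(p == 0.0 for p in ps):
        return 0.0
    return _optimize_t(counts_models, t_hint=float(np.mean(ps)))


# ----------------------------------------------------------------------
# saturation diagnostic


def saturation_profile(
    aln: AlignedSequences,
    model: SubstModel,
    subset: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> dict[str, dict[str, float | bool]]:
    """Per-codon-position saturation table over all sequence pairs.

    For each position class (1, 2, 3; or 'all' without annotation):
    mean p-distance, mean corrected distance, their ratio R (R = 1 when
    the mean corrected distance is 0; a pair whose corrected distance
    is unresolvable counts as ratio 0), and a flag set when the mean
    per-pair ratio within the most divergent quartile of pairs (ranked
    by full-alignment corrected distance) falls below ``threshold``.
    """
    labels = list(subset) if subset is not None else aln.labels
    if len(labels) < 2:
        raise ValueError("saturation profile needs at least 2 sequences")
    if aln.codon_positions is not None:
        classes = {
            str(c): [i for i, cp in enumerate(aln.codon_positions) if cp == c]
            for c in (1, 2, 3)
        }
        classes = {c: cols for c, cols in classes.items() if cols}
    else:
        classes = {"all": list(range(aln.length))}

    pairs = [(labels[i], labels[j]) for i in range(len(labels))
             for j in range(i + 1, len(labels))]

    overall: list[float] = []
    per_class: dict[str, list[tuple[float, float]]] = {c: [] for c in classes}
    for a, b in pairs:
        try:
            overall.append(ml_distance(aln.seqs[a], aln.seqs[b], model))
        except SaturatedError:
            overall.append(math.inf)
        for cname, cols in classes.items():
            sa = "".join(aln.seqs[a][i] for i in cols)
            sb = "".join(aln.seqs[b][i] for i in cols)
            p = p_distance(sa, sb)
            try:
                d = ml_distance(sa, sb, model)
            except SaturatedError:
                d = math.inf
            per_class[cname].append((p, d))

    q = max(1, math.ceil(len(pairs) / 4))
    top_idx = list(np.argsort(overall)[::-1][:q])

    out: dict[str, dict[str, float | bool]] = {}
    for cname, vals in per_class.items():
        ps = np.array([v[0] for v in vals])
        ds = np.array([v[1] for v in vals])
        finite = np.isfinite(ds)
        mean_p = float(ps.mean())
        mean_d = float(ds[finite].mean()) if finite.any() else math.inf
        if mean_d == 0.0:
            ratio = 1.0
        elif math.isinf(mean_d):
            ratio = 0.0
        else:
            ratio = mean_p / mean_d
        pair_ratio = []
        for i in top_idx:
            p, d = vals[i]
            if d == 0.0:
                pair_ratio.append(1.0)
            elif math.isinf(d):
                pair_ratio.append(0.0)
            else:
                pair_ratio.append(p / d)
        flagged = bool(np.mean(pair_ratio) < threshold)
        out[cname] = {
            "mean_p": mean_p,
            "mean_d": mean_d,
            "ratio": ratio,
            "saturated": flagged,
        }
    return out


# ----------------------------------------------------------------------
# file I/O


def read_fasta(path, codon_positions=None, partitions=None) -> AlignedSequences:
    """Read an aligned FASTA file into :class:`AlignedSequences`."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate sequence label {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return AlignedSequences(seqs, codon_positions, partitions)


def write_fasta(aln: AlignedSequences, path) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_partition_file(path) -> list[tuple[str, int, int, SubstModel]]:
    """YAML list of {name, start, end, model: {...}} partition entries.

    ``model`` keys: family (JC69|K80|HKY|GTR), kappa, rates, freqs,
    p_inv, alpha, ncat; ranges are 1-based inclusive.
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    out = []
    for entry in entries:
        m = entry.get("model", {}) or {}
        family = str(m.get("family", "JC69")).upper()
        kw = {
            "p_inv": float(m.get("p_inv", 0.0)),
            "alpha": None if m.get("alpha") is None else float(m["alpha"]),
            "ncat": int(m.get("ncat", 4)),
        }
        if family == "JC69":
            model = SubstModel.jc69(**kw)
        elif family == "K80":
            model = SubstModel.k80(float(m["kappa"]), **kw)
        elif family == "HKY":
            model = SubstModel.hky(float(m["kappa"]), tuple(m["freqs"]), **kw)
        elif family == "GTR":
            model = SubstModel.gtr(tuple(m["rates"]), tuple(m["freqs"]), **kw)
        else:
            raise ValueError(f"unknown model family {family!r}")
        out.append((entry["name"], int(entry["start"]), int(entry["end"]), model))
    return out
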