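"""Marker-signature cell typing.

Cells are assigned to holoclone-forming, clonogenic or terminally
differentiated states from published marker lists by a semi-supervised EM in
the spirit of signature-based annotators: each signature gene follows a
two-component Gaussian over normalized expression (elevated in the owning
type, background elsewhere), cell-type posteriors are the E-step, component
moments the M-step, and cells whose best posterior stays below a cutoff are
left "unknown".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .preprocess import NormalizedMatrix

TYPES = ("holoclone", "clonogenic", "differentiated")

# the published clonogenic list prints "ITB1"; map it to the standard symbol
SYMBOL_ALIASES = {"ITB1": "ITGB1"}


class SignatureError(ValueError):
    pass


@dataclass
class SignatureSet:
    """Named, disjoint marker-gene lists."""

    signatures: dict

    def __post_init__(self):
        seen = {}
        for name, genes in self.signatures.items():
            for g in genes:
                if g in seen:
                    raise SignatureError(
                        f"gene {g!r} appears in both {seen[g]!r} and {name!r}")
                seen[g] = name

    def resolved(self, panel) -> dict:
        """Signature -> panel row indices, applying symbol aliases."""
        lookup = {s: i for i, s in enumerate(panel)}
        out = {}
        for name, genes in self.signatures.items():
            idx = []
            for g in genes:
                g2 = SYMBOL_ALIASES.get(g, g)
                if g2 in lookup:
                    idx.append(lookup[g2])
            if not idx:
                raise SignatureError(f"signature {name!r} has no genes in panel")
            out[name] = np.asarray(sorted(set(idx)), dtype=int)
        return out

    @classmethod
    def from_tsv(cls, path_or_name) -> "SignatureSet":
        """Two-column TSV (signature name, gene symbol)."""
        try:
            text = resources.files("rockisc.data").joinpath(str(path_or_name)).read_text()
        except (FileNotFoundError, TypeError):
            text = open(path_or_name).read()
        sigs = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            name, gene = line.split("\t")
            sigs.setdefault(name, []).append(gene.strip())
        return cls(sigs)

    @classmethod
    def default(cls) -> "SignatureSet":
        """The full published holoclone / clonogenic / differentiated lists."""
        return cls.from_tsv("signatures_full.tsv")

    @classmethod
    def core(cls) -> "SignatureSet":
        """The five-marker holoclone variant of the published lists."""
        return cls.from_tsv("signatures_core.tsv")


@dataclass
class TypeAssignment:
    labels: np.ndarray                 # per-cell type or "unknown"
    posterior: pd.DataFrame            # cells x types
    converged: bool = True
    log_likelihood: list = field(default_factory=list)


def score_signatures(nm: NormalizedMatrix, sigs: SignatureSet = None) -> pd.DataFrame:
    """Mean residual of each signature's genes per cell (the argmax oracle)."""
    sigs = sigs or SignatureSet.default()
    resolved = sigs.resolved(nm.gene_symbols)
    scores = {name: nm.residuals[idx].mean(axis=0) for name, idx in resolved.items()}
    return pd.DataFrame(scores, index=pd.Index(nm.barcodes, name="barcode"))


def classify_em(nm: NormalizedMatrix, sigs: SignatureSet = None,
                max_iter: int = 100, tol: float = 1e-6,
                allow_unknown: bool = True, unknown_cutoff: float = 0.5,
                min_effect_size: float = 0.8, seed: int = 0) -> TypeAssignment:
    """Semi-supervised two-component Gaussian EM over signature genes.

    After convergence, genes whose elevated/background separation falls below
    *min_effect_size* pooled standard deviations are treated as uninformative
    and dropped before the final posterior, so signal-free data yields
    near-uniform posteriors (hence "unknown" cells) instead of confident
    labels fitted to noise.
    """
    sigs = sigs or SignatureSet.default()
    resolved = sigs.resolved(nm.gene_symbols)
    types = [t for t in TYPES if t in resolved] or list(resolved)
    genes = np.concatenate([resolved[t] for t in types])
    owner = np.concatenate([np.full(len(resolved[t]), k) for k, t in enumerate(types)])
    X = nm.residuals[genes]                      # m genes x n cells
    m, n = X.shape
    K = len(types)

    # moment initialization: elevated component from the top quartile
    q75 = np.quantile(X, 0.75, axis=1)
    mu1 = np.array([X[g][X[g] >= q75[g]].mean() for g in range(m)])
    mu0 = np.array([X[g][X[g] < q75[g]].mean() if (X[g] < q75[g]).any() else X[g].mean()
                    for g in range(m)])
    sd = np.maximum(X.std(axis=1), 1e-3)
    s1, s0 = sd.copy(), sd.copy()
    log_pi = np.full(K, -np.log(K))

    own = owner[:, None] == np.arange(K)[None, :]   # m x K
    ll_trace = []
    prev_ll = -np.inf
    converged = False
    for _it in range(max_iter):
        # E-step: per-cell log joint for each type
        log1 = -0.5 * ((X - mu1[:, None]) / s1[:, None]) ** 2 - np.log(s1[:, None]) \
            - 0.5 * np.log(2 * np.pi)
        log0 = -0.5 * ((X - mu0[:, None]) / s0[:, None]) ** 2 - np.log(s0[:, None]) \
            - 0.5 * np.log(2 * np.pi)
        # cells x K: sum over genes of (own ? log1 : log0)
        joint = (own.T @ log1 + (~own).T @ log0).T + log_pi[None, :]
        ll = logsumexp(joint, axis=1)
        post = np.exp(joint - ll[:, None])
        total_ll = float(ll.sum())
        ll_trace.append(total_ll)
        # the mean-ordering constraint can nudge the likelihood by a few ulp
        if total_ll < prev_ll - 1e-5 * abs(prev_ll):
            warnings.warn("EM log-likelihood decreased; stopping")
            break
        if abs(total_ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = total_ll

        # M-step: per-gene weighted moments, elevated mean kept >= background
        w_elev = post[:, owner].T                  # m x n: weight of owning type
        w_back = 1.0 - w_elev
        se = np.maximum(w_elev.sum(axis=1), 1e-9)
        sb = np.maximum(w_back.sum(axis=1), 1e-9)
        mu1 = (w_elev * X).sum(axis=1) / se
        mu0 = (w_back * X).sum(axis=1) / sb
        mu1 = np.maximum(mu1, mu0)
        s1 = np.sqrt(np.maximum((w_elev * (X - mu1[:, None]) ** 2).sum(axis=1) / se, 1e-6))
        s0 = np.sqrt(np.maximum((w_back * (X - mu0[:, None]) ** 2).sum(axis=1) / sb, 1e-6))
        log_pi = np.log(np.maximum(post.mean(axis=0), 1e-12))
        log_pi -= logsumexp(log_pi)
    else:
        warnings.warn("EM did not converge; returning best assignment")

    # final posterior over informative genes only
    pooled_sd = np.sqrt(0.5 * (s1 ** 2 + s0 ** 2))
    informative = (mu1 - mu0) / np.maximum(pooled_sd, 1e-12) >= min_effect_size
    if informative.any():
        keep = np.flatnonzero(informative)
        log1 = -0.5 * ((X[keep] - mu1[keep, None]) / s1[keep, None]) ** 2 \
            - np.log(s1[keep, None]) - 0.5 * np.log(2 * np.pi)
        log0 = -0.5 * ((X[keep] - mu0[keep, None]) / s0[keep, None]) ** 2 \
            - np.log(s0[keep, None]) - 0.5 * np.log(2 * np.pi)
        joint = (own[keep].T @ log1 + (~own[keep]).T @ log0).T + log_pi[None, :]
        post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    else:
        post = np.full((n, K), 1.0 / K)

    labels = np.asarray([types[k] for k in post.argmax(axis=1)], dtype=object)
    if allow_unknown:
        labels[post.max(axis=1) < unknown_cutoff] = "unknown"
    posterior = pd.DataFrame(post, columns=types,
                             index=pd.Index(nm.barcodes, name="barcode"))
    return TypeAssignment(labels=labels, posterior=posterior,
                          converged=converged, log_likelihood=ll_trace)


@dataclass
class ProportionVector:
    """Type proportions over assigned (non-unknown) cells."""

    values: np.ndarray
    types: tuple = TYPES
    n_cells: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise SignatureError("proportions must sum to 1")


def proportions(labels, mask=None, types=TYPES) -> ProportionVector:
    """Per-type fractions among assigned cells (optionally within *mask*)."""
    labels = np.asarray(labels, dtype=object)
    if mask is not None:
        labels = labels[np.asarray(mask)]
    assigned = labels[np.isin(labels, types)]
    if len(assigned) == 0:
        raise SignatureError("no assigned cells in selection")
    counts = np.array([(assigned == t).sum() for t in types], dtype=float)
    return ProportionVector(values=counts / counts.sum(), types=tuple(types),
                            n_cells=int(len(assigned)))
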