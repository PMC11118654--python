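"""Reference-signature assignment and per-mutation attribution.

Per-sample activities are fit by a forward-stagewise sparse regression:
signatures enter the support only when they raise the reconstruction
cosine similarity by more than an addition penalty, and are pruned when
their removal costs no more than a removal penalty; the activities on the
final support come from nonnegative least squares, with exact zeros
elsewhere.  Cohort rules mirror common practice for reference refitting:
globally excluded signatures, indel-triggered rescues (ID6 enables SBS3,
ID3 enables SBS92), and a microsatellite-instability rescue set.
Per-mutation probabilities follow Bayes' rule on the reconstructed
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

_EPS = np.finfo(np.float64).eps

#: mismatch-repair-deficiency signatures allowed under the MSI rescue
MSI_SIGNATURES = ("SBS6", "SBS14", "SBS15", "SBS20", "SBS21", "SBS26", "SBS44")

#: signatures excluded cohort-wide from decomposition and assignment
DEFAULT_EXCLUSIONS = ("SBS23", "SBS32")

#: (trigger signature in the indel catalog, substitution signature it enables)
DEFAULT_RESCUE_RULES = (("ID6", "SBS3"), ("ID3", "SBS92"))


@dataclass
class ReferenceSignatureSet:
    """Named reference profiles over a schema plus candidate-rule metadata."""

    schema: object
    profiles: pd.DataFrame  # categories x signatures, columns sum to 1
    global_exclusions: frozenset[str] = frozenset(DEFAULT_EXCLUSIONS)
    rescue_rules: tuple[tuple[str, str], ...] = DEFAULT_RESCUE_RULES
    msi_rescue_set: tuple[str, ...] = ("SBS33",) + MSI_SIGNATURES

    def __post_init__(self):
        P = self.profiles.to_numpy(dtype=float)
        if (P < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        sums = P.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature profiles must each sum to 1")
        self.global_exclusions = frozenset(self.global_exclusions)

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def subset(self, names) -> "ReferenceSignatureSet":
        return ReferenceSignatureSet(
            self.schema,
            self.profiles[list(names)],
            self.global_exclusions,
            self.rescue_rules,
            self.msi_rescue_set,
        )


@dataclass
class AssignmentConfig:
    """Similarity penalties of the sparse fit, in cosine units.

    The removal penalty must not exceed the addition penalty in play:
    otherwise the backward phase immediately prunes barely-admitted
    signatures, and relaxing the addition gate would paradoxically lower
    sensitivity.  The relaxed configuration therefore caps the removal
    penalty at the relaxed addition penalty.
    """

    add_penalty: float = 0.05
    remove_penalty: float = 0.01
    relaxed_add_penalty: float = 0.01

    def __post_init__(self):
        for p in (self.add_penalty, self.remove_penalty, self.relaxed_add_penalty):
            if not (0 <= p < 1):
                raise ValueError("penalties must lie in [0, 1)")

    def relaxed(self) -> "AssignmentConfig":
        return AssignmentConfig(
            add_penalty=self.relaxed_add_penalty,
            remove_penalty=min(self.remove_penalty, self.relaxed_add_penalty),
            relaxed_add_penalty=self.relaxed_add_penalty,
        )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 0 or nb <= 0:
        return 0.0
    return float(a @ b / (na * nb))


def _fit_support(P: np.ndarray, y: np.ndarray, support: list[int]):
    if not support:
        return np.zeros(0), 0.0
    x, _ = nnls(P[:, support], y)
    return x, _cosine(P[:, support] @ x, y)


def assign_activities(
    profile,
    candidates: ReferenceSignatureSet,
    config: AssignmentConfig | None = None,
):
    """Sparse nonnegative activities of ``candidates`` for one sample profile.

    Forward phase: greedily add the signature with the largest cosine
    gain while the gain exceeds ``add_penalty`` (ties: larger gain, then
    lexicographic name).  Backward phase: repeatedly drop the cheapest
    signature while the similarity loss is at most ``remove_penalty``.
    Returns (activities Series with exact zeros off-support,
    reconstruction cosine similarity).
    """
    config = config or AssignmentConfig()
    names = candidates.names
    P = candidates.profiles.to_numpy(dtype=float)
    y = np.asarray(profile, dtype=float)
    if y.shape[0] != P.shape[0]:
        raise ValueError("profile and candidate profiles must share the schema")
    if len(names) == 0:
        raise ValueError("empty candidate set")
    zero = pd.Series(np.zeros(len(names)), index=names, name="activity")
    if y.sum() <= 0:
        return zero, 0.0

    order = {n: i for i, n in enumerate(names)}
    support: list[int] = []
    current = 0.0
    seen: set[frozenset[int]] = set()
    while True:
        # forward stagewise additions
        while len(support) < len(names):
            best_gain, best_idx = -np.inf, None
            for n in sorted(names):  # lexicographic tie-break via stable iteration
                i = order[n]
                if i in support:
                    continue
                _, cos = _fit_support(P, y, support + [i])
                gain = cos - current
                if gain > best_gain + 1e-12:
                    best_gain, best_idx = gain, i
            if best_idx is None or best_gain <= config.add_penalty:
                break
            support.append(best_idx)
            _, current = _fit_support(P, y, support)
        # backward pruning
        pruned = False
        while len(support) > 1:
            best_loss, best_idx = np.inf, None
            for i in sorted(support, key=lambda i: names[i]):
                trial = [j for j in support if j != i]
                _, cos = _fit_support(P, y, trial)
                loss = current - cos
                if loss < best_loss - 1e-12:
                    best_loss, best_idx = loss, i
            if best_idx is None or best_loss > config.remove_penalty:
                break
            support.remove(best_idx)
            _, current = _fit_support(P, y, support)
            pruned = True
        key = frozenset(support)
        if not pruned or key in seen:
            break  # fixed point of both phases (or cycle protection)
        seen.add(key)

    x, current = _fit_support(P, y, support)
    acts = zero.copy()
    for pos, i in enumerate(support):
        acts.iloc[i] = x[pos]
    return acts, current


def assign_cohort(
    catalog,
    candidates_per_sample: dict[str, list[str]] | None,
    reference: ReferenceSignatureSet,
    config: AssignmentConfig | None = None,
) -> pd.DataFrame:
    """Activity matrix (signatures x samples) for a whole catalog.

    ``candidates_per_sample`` maps sample id to its candidate labels; when
    None, all non-excluded reference signatures are candidates everywhere.
    """
    config = config or AssignmentConfig()
    default = [n for n in reference.names if n not in reference.global_exclusions]
    out = pd.DataFrame(
        0.0, index=reference.names, columns=catalog.sample_ids
    )
    for sample in catalog.sample_ids:
        cand = candidates_per_sample.get(sample, default) if candidates_per_sample else default
        acts, _ = assign_activities(
            catalog.counts[sample].to_numpy(), reference.subset(cand), config
        )
        out.loc[acts.index, sample] = acts.to_numpy()
    return out


def decompose_denovo(
    denovo_signatures: pd.DataFrame,
    reference: ReferenceSignatureSet,
    config: AssignmentConfig | None = None,
) -> dict[str, dict]:
    """Express each de novo signature as a sparse mixture of references.

    Globally excluded reference signatures never receive weight.  Weights
    are normalized to sum to 1; the decomposition cosine similarity is
    reported alongside.
    """
    config = config or AssignmentConfig()
    allowed = [n for n in reference.names if n not in reference.global_exclusions]
    ref = reference.subset(allowed)
    result: dict[str, dict] = {}
    for name in denovo_signatures.columns:
        y = denovo_signatures[name].to_numpy(dtype=float)
        acts, cos = assign_activities(y, ref, config)
        total = acts.sum()
        weights = (acts / total if total > 0 else acts).to_dict()
        result[name] = {
            "weights": {k: v for k, v in weights.items() if v > 0},
            "similarity": cos,
        }
    return result


def build_candidate_sets(
    samples,
    decomposed_labels,
    id_activities: pd.DataFrame | None,
    msi_flags: dict[str, bool] | None,
    reference: ReferenceSignatureSet,
) -> dict[str, list[str]]:
    """Per-sample candidate signatures from the cohort decomposition + rules.

    Base set: the decomposed reference labels minus global exclusions.
    Rescues: each (trigger, label) rule adds ``label`` when the trigger
    signature has positive activity in the sample's indel fit; the MSI
    rescue set is added for flagged samples.
    """
    known = set(reference.names)
    for trigger, label in reference.rescue_rules:
        if label not in known:
            raise ValueError(f"rescue rule adds unknown signature {label!r}")
    base = sorted(
        set(decomposed_labels) - set(reference.global_exclusions)
    )
    out: dict[str, list[str]] = {}
    for sample in samples:
        cand = list(base)
        for trigger, label in reference.rescue_rules:
            if id_activities is None or trigger not in id_activities.index:
                continue
            if sample in id_activities.columns and id_activities.loc[trigger, sample] > 0:
                if label not in cand:
                    cand.append(label)
        if msi_flags and msi_flags.get(sample, False):
            for label in reference.msi_rescue_set:
                if label not in cand:
                    cand.append(label)
        out[sample] = sorted(c for c in cand if c in known)
    return out


class MutationProbabilityTable:
    """P(signature | context, sample) over the reconstructed profile."""

    def __init__(self, probabilities: np.ndarray, samples, categories, signatures, defined: np.ndarray):
        self.probabilities = probabilities  # samples x categories x signatures
        self.samples = list(samples)
        self.categories = list(categories)
        self.signatures = list(signatures)
        self.defined = defined  # samples x categories; False where denominator was 0

    def for_sample(self, sample: str) -> pd.DataFrame:
        i = self.samples.index(sample)
        return pd.DataFrame(
            self.probabilities[i], index=self.categories, columns=self.signatures
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.samples):
            defined = np.flatnonzero(self.defined[i])
            for c in defined:
                for j, sig in enumerate(self.signatures):
                    rows.append((s, self.categories[c], sig, self.probabilities[i, c, j]))
        return pd.DataFrame(rows, columns=["sample", "context", "signature", "probability"])


def mutation_probabilities(
    activities: pd.DataFrame, reference: ReferenceSignatureSet
) -> MutationProbabilityTable:
    """Bayes attribution: signature share of the reconstructed count per context.

    P(s | c, j) = profile[c, s] * activity[s, j] / sum_s' profile[c, s'] *
    activity[s', j]; contexts with zero reconstructed count are flagged
    undefined rather than given probabilities.
    """
    sigs = [s for s in activities.index if s in reference.profiles.columns]
    if len(sigs) != len(activities.index):
        missing = set(activities.index) - set(sigs)
        raise KeyError(f"activities reference unknown signatures: {sorted(missing)}")
    P = reference.profiles[sigs].to_numpy(dtype=float)  # c x s
    A = activities.loc[sigs].to_numpy(dtype=float)  # s x j
    weighted = P[None, :, :] * A.T[:, None, :]  # j x c x s
    denom = weighted.sum(axis=2, keepdims=True)
    defined = denom[:, :, 0] > 0
    probs = np.divide(weighted, denom, out=np.zeros_like(weighted), where=denom > 0)
    return MutationProbabilityTable(
        probs, activities.columns, reference.profiles.index, sigs, defined
    )


def attribute_driver_mutations(
    drivers: pd.DataFrame,
    table: MutationProbabilityTable,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top signature per driver mutation plus per-gene signature proportions.

    ``drivers`` needs columns sample, category, gene.  A mutation is
    confident only when its best probability strictly exceeds
    ``threshold``; argmax ties break lexicographically by signature name.
    """
    sig_order = np.argsort(table.signatures)  # lexicographic scan order
    cat_index = {c: i for i, c in enumerate(table.categories)}
    rows = []
    for rec in drivers.itertuples(index=False):
        if rec.category not in cat_index:
            raise KeyError(f"context {rec.category!r} absent from probability table")
        i = table.samples.index(rec.sample)
        c = cat_index[rec.category]
        if not table.defined[i, c]:
            rows.append((rec.sample, rec.gene, rec.category, None, np.nan, False))
            continue
        p = table.probabilities[i, c]
        best = sig_order[int(np.argmax(p[sig_order]))]
        rows.append(
            (
                rec.sample,
                rec.gene,
                rec.category,
                table.signatures[best],
                float(p[best]),
                bool(p[best] > threshold),
            )
        )
    assigned = pd.DataFrame(
        rows,
        columns=["sample", "gene", "category", "top_signature", "probability", "confident"],
    )
    attributed = assigned.dropna(subset=["probability"])
    per_gene = (
        attributed.groupby(["gene", "top_signature"]).size().unstack(fill_value=0)
    )
    per_gene = per_gene.div(per_gene.sum(axis=1), axis=0)
    return assigned, per_gene
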