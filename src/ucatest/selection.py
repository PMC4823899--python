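"""The common-ancestry model-selection ("UCA") test.

Common ancestry is modelled as one tree connecting all sequences;
independent origins (IO) as separate trees for the groups of a partition.
Each hypothesis is scored by the best AIC over a set of substitution
models, where a fit's free-parameter count k is the model's parameter count
plus one per branch length, and

    delta_AIC = AIC(IO) - AIC(UCA)

so positive values favour common ancestry; a difference above 10 is
conventionally "essentially no support" for the losing hypothesis.  Both
hypotheses are evaluated on the same alignment (information criteria are
only comparable on common data); the separate-alignment variant exists as
an explicitly flagged cross-alignment comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import SequenceSet
from .models import MODEL_NAMES, get_model
from .msa import progressive_align, strip_gaps
from .partition import Partition, as_partition
from .phylo.likelihood import ModelPrep, TreeLikelihood
from .phylo.optimize import FitResult, _EncodedAlignment, fit_on_tree
from .phylo.search import ml_tree

DEFAULT_MODEL_SET: Tuple[str, ...] = MODEL_NAMES
DEFAULT_TOPOLOGY_MODEL = "LG"
STRONG_SUPPORT_DELTA = 10.0


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2LnL."""
    return 2.0 * k - 2.0 * loglik


def bic(loglik: float, k: int, n_sites: int) -> float:
    """Bayesian information criterion, k log(N) - 2LnL, with N the number
    of alignment columns (the data points of a phylogenetic fit)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return k * math.log(n_sites) - 2.0 * loglik


@dataclass
class HypothesisFit:
    """Best fit for one hypothesis: a single tree, or one tree per group."""

    hypothesis: str  # "UCA" or "IO"
    group_fits: Dict[str, FitResult]
    n_sites: int
    #: adjustment for parameters shared across groups (forced homogeneity)
    k_correction: int = 0

    @property
    def loglik(self) -> float:
        return sum(f.loglik for f in self.group_fits.values())

    @property
    def k(self) -> int:
        return sum(f.k for f in self.group_fits.values()) + self.k_correction

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    @property
    def bic(self) -> float:
        return sum(
            bic(f.loglik, f.k, self.n_sites) for f in self.group_fits.values()
        )

    @property
    def best_models(self) -> Dict[str, str]:
        return {g: f.model.name for g, f in self.group_fits.items()}

    @property
    def saturated(self) -> Dict[str, List[str]]:
        return {g: f.saturated for g, f in self.group_fits.items()}


def _best_fit_on_shared_topology(
    encoded: _EncodedAlignment,
    model_names: Sequence[str],
    topology_model: str,
    extra_start_trees: Sequence = (),
) -> FitResult:
    """ProtTest-style scoring: one topology search under a reference model,
    then every candidate model fitted on that fixed topology; best by AIC.

    ``extra_start_trees`` adds informed candidate topologies (e.g. the
    joined per-group trees, which the single-tree hypothesis nests); the
    reference model picks the best start before the model chain runs.
    """
    ref = ml_tree(None, get_model(topology_model), encoded=encoded)
    alts = []
    for tree in extra_start_trees:
        alt = fit_on_tree(encoded, tree, get_model(topology_model))
        alts.append(alt)
        if alt.loglik > ref.loglik:
            ref, alt = alt, ref
            alts[-1] = alt
    best: Optional[FitResult] = None
    start_tree = ref.tree
    prev_alpha = prev_pinv = None
    for name in model_names:
        if name == topology_model:
            fit = ref
        else:
            # warm start from the previous model's optimised branch lengths
            # and, where shared, its rate parameters
            model = get_model(name)
            if model.alpha is not None and prev_alpha is not None:
                model = model.with_parameters(alpha=prev_alpha)
            if model.p_inv is not None and prev_pinv is not None:
                model = model.with_parameters(p_inv=prev_pinv)
            fit = fit_on_tree(encoded, start_tree, model)
        start_tree = fit.tree
        if fit.model.alpha is not None:
            prev_alpha = fit.model.alpha
        if fit.model.p_inv is not None:
            prev_pinv = fit.model.p_inv
        if best is None or fit.aic < best.aic:
            best = fit
    # the winning model may prefer the runner-up start topology
    for alt in alts:
        refit = fit_on_tree(encoded, alt.tree, get_model(best.model.name))
        if refit.aic < best.aic:
            best = refit
    return best


def _fit_homogeneous_io(
    group_encoded: Dict[str, _EncodedAlignment],
    group_trees: Dict[str, object],
    model_names: Sequence[str],
) -> Dict[str, FitResult]:
    """IO fits forced to share one substitution model across groups.

    Frequencies (+F) are pooled over all groups; alpha / p_inv are chosen
    to maximise the summed group log-likelihood; branch lengths stay free
    per group.  The shared model's parameters are counted once.
    """
    from .phylo.optimize import empirical_frequencies

    best_total: Optional[float] = None
    best_fits: Dict[str, FitResult] = {}
    pooled_pat = np.hstack([e.patterns for e in group_encoded.values()])
    pooled_cnt = np.concatenate([e.counts for e in group_encoded.values()])
    for name in model_names:
        model = get_model(name)
        if model.frequencies_estimated:
            model = model.with_frequencies(
                empirical_frequencies(pooled_pat, pooled_cnt)
            )
        engines = {
            g: TreeLikelihood(
                e.patterns, e.counts, e.row_index, group_trees[g].copy(), ModelPrep(model)
            )
            for g, e in group_encoded.items()
        }
        for eng in engines.values():
            eng.optimize_branches()

        current = {"model": model}

        def total_ll(alpha=None, p_inv=None) -> float:
            m = current["model"]
            if alpha is not None:
                m = m.with_parameters(alpha=alpha)
            if p_inv is not None:
                m = m.with_parameters(p_inv=p_inv)
            current["model"] = m
            tot = 0.0
            for eng in engines.values():
                eng.prep = eng.prep.replace_rate_parameters(m)
                tot += eng.loglik()
            return tot

        total = sum(eng.loglik() for eng in engines.values())
        if model.alpha is not None or model.p_inv is not None:
            for _ in range(3):
                prev = total
                if model.alpha is not None:
                    res = minimize_scalar(
                        lambda x: -total_ll(alpha=math.exp(x)),
                        bounds=(math.log(0.02), math.log(100.0)),
                        method="bounded",
                        options={"xatol": 1e-3, "maxiter": 25},
                    )
                    total = -res.fun
                    total_ll(alpha=math.exp(float(res.x)))
                if model.p_inv is not None:
                    res = minimize_scalar(
                        lambda x: -total_ll(p_inv=x),
                        bounds=(1e-6, 0.9),
                        method="bounded",
                        options={"xatol": 1e-3, "maxiter": 25},
                    )
                    total = -res.fun
                    total_ll(p_inv=float(res.x))
                total = sum(
                    eng.optimize_branches(max_sweeps=10) for eng in engines.values()
                )
                if total - prev < 1e-3:
                    break
        model = current["model"]
        from .models import parameter_count

        shared_k = parameter_count(model)
        total_k = shared_k + sum(
            eng.tree.n_branches for eng in engines.values()
        )
        total_aic = aic(total, total_k)
        if best_total is None or total_aic < best_total:
            best_total = total_aic
            fits = {}
            for g, eng in engines.items():
                eng.write_lengths()
                fits[g] = FitResult(
                    eng.tree,
                    model,
                    float(eng.loglik()),
                    group_encoded[g].n_sites,
                    saturated=eng.saturated_branches,
                )
            best_fits = fits
    return best_fits


def fit_hypothesis(
    alignment: SequenceSet,
    partition: Optional[Partition | Dict] = None,
    model_names: Sequence[str] = DEFAULT_MODEL_SET,
    topology_model: str = DEFAULT_TOPOLOGY_MODEL,
) -> HypothesisFit:
    """Best per-hypothesis fit on a shared alignment.

    With no partition (or a single group) this is the common-ancestry
    hypothesis: one tree over everything.  With a partition of two or more
    groups each group is fitted independently on its rows of the shared
    alignment (columns kept as they are, so N matches the UCA fit) and is
    free to pick its own best model; totals are sums over groups.
    """
    if not alignment.is_aligned:
        raise ValueError("input must be aligned")
    single = partition is None
    if not single:
        partition = as_partition(partition)
        partition.validate_against(alignment.ids)
        single = partition.n_groups == 1
    if single:
        encoded = _EncodedAlignment(alignment)
        best = _best_fit_on_shared_topology(encoded, model_names, topology_model)
        return HypothesisFit("UCA", {"all": best}, encoded.n_sites)
    fits: Dict[str, FitResult] = {}
    for name in partition.names:
        members = partition.members(name)
        if len(members) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 sequences")
        sub = alignment.subset(members)
        encoded = _EncodedAlignment(sub)
        fits[name] = _best_fit_on_shared_topology(encoded, model_names, topology_model)
    return HypothesisFit("IO", fits, alignment.n_columns)


def _classify(delta_aic_value: float) -> str:
    if delta_aic_value > STRONG_SUPPORT_DELTA:
        return "strong-UCA"
    if delta_aic_value > 0.0:
        return "weak-UCA"
    return "favours-IO"


@dataclass
class UcaTestResult:
    """Outcome of the delta-AIC test on one shared alignment."""

    uca: HypothesisFit
    io: HypothesisFit
    cross_alignment: bool = False

    @property
    def delta_aic(self) -> float:
        return self.io.aic - self.uca.aic

    @property
    def delta_bic(self) -> float:
        return self.io.bic - self.uca.bic

    @property
    def classification(self) -> str:
        return _classify(self.delta_aic)

    def to_dict(self) -> dict:
        return {
            "delta_aic": self.delta_aic,
            "delta_bic": self.delta_bic,
            "classification": self.classification,
            "uca": {
                "loglik": self.uca.loglik,
                "k": self.uca.k,
                "aic": self.uca.aic,
                "bic": self.uca.bic,
                "n_sites": self.uca.n_sites,
                "models": self.uca.best_models,
                "saturated": self.uca.saturated,
            },
            "io": {
                "loglik": self.io.loglik,
                "k": self.io.k,
                "aic": self.io.aic,
                "bic": self.io.bic,
                "n_sites": self.io.n_sites,
                "models": self.io.best_models,
                "saturated": self.io.saturated,
            },
            "cross_alignment": self.cross_alignment,
        }

    def summary(self) -> str:
        lines = [
            "Common-ancestry model-selection test",
            "=" * 64,
            f"{'':16}{'UCA':>22}{'IO':>26}",
            f"{'LnL':16}{self.uca.loglik:>22.3f}{self.io.loglik:>26.3f}",
            f"{'k':16}{self.uca.k:>22d}{self.io.k:>26d}",
            f"{'AIC':16}{self.uca.aic:>22.3f}{self.io.aic:>26.3f}",
            f"{'BIC':16}{self.uca.bic:>22.3f}{self.io.bic:>26.3f}",
            f"{'best model(s)':16}{','.join(self.uca.best_models.values()):>22}"
            f"{','.join(self.io.best_models.values()):>26}",
            "-" * 64,
            f"delta_AIC (IO - UCA): {self.delta_aic:.3f}",
            f"delta_BIC (IO - UCA): {self.delta_bic:.3f}",
            f"classification:       {self.classification}",
        ]
        if self.cross_alignment:
            lines.append(
                "note: cross-alignment comparison - no probabilistic interpretation"
            )
        return "\n".join(lines)


def delta_aic_test(
    alignment: SequenceSet,
    partition: Partition | Dict,
    model_names: Sequence[str] = DEFAULT_MODEL_SET,
    topology_model: str = DEFAULT_TOPOLOGY_MODEL,
    force_homogeneous: bool = False,
) -> UcaTestResult:
    """The UCA test: one tree versus per-group trees on one alignment.

    ``force_homogeneous`` constrains the IO hypothesis to one shared
    substitution model across groups (branch lengths stay free), isolating
    the independent-origins assumption from substitution-model
    heterogeneity.
    """
    partition = as_partition(partition)
    if partition.n_groups == 1:
        uca_fit = fit_hypothesis(alignment, None, model_names, topology_model)
        return UcaTestResult(uca_fit, uca_fit)
    if force_homogeneous:
        io_fit = _fit_hypothesis_homogeneous(
            alignment, partition, model_names, topology_model
        )
    else:
        io_fit = fit_hypothesis(alignment, partition, model_names, topology_model)
    # the single-tree hypothesis nests the per-group structure (join the
    # group trees by a saturated branch), so offer that tree as an informed
    # starting topology alongside the NJ/NNI search
    from .phylo.likelihood import MAX_BRANCH_LENGTH, MIN_BRANCH_LENGTH
    from .phylo.tree import Node, Tree

    root = Node()
    # canonical order (by leaf labels) so the result does not depend on
    # group naming or dictionary order
    for fit in sorted(
        io_fit.group_fits.values(), key=lambda f: sorted(f.tree.leaf_labels())
    ):
        sub = fit.tree.copy().root
        sub.length = MAX_BRANCH_LENGTH / 2.0
        # binarise a trifurcating group root so the joined tree is a fully
        # resolved binary tree (same branch-parameter count as any other
        # candidate topology)
        while len(sub.children) > 2:
            inner = Node(length=MIN_BRANCH_LENGTH)
            for child in sub.children[1:3]:
                inner.add(child)
            sub.children = [sub.children[0]] + sub.children[3:]
            sub.add(inner)
        root.add(sub)
    joined = Tree(root)
    encoded = _EncodedAlignment(alignment)
    uca_best = _best_fit_on_shared_topology(
        encoded, model_names, topology_model, extra_start_trees=(joined,)
    )
    uca_fit = HypothesisFit("UCA", {"all": uca_best}, encoded.n_sites)
    return UcaTestResult(uca_fit, io_fit)


def _fit_hypothesis_homogeneous(alignment, partition, model_names, topology_model):
    group_encoded = {}
    group_trees = {}
    for name in partition.names:
        sub = alignment.subset(partition.members(name))
        enc = _EncodedAlignment(sub)
        group_encoded[name] = enc
        group_trees[name] = ml_tree(None, get_model(topology_model), encoded=enc).tree
    fits = _fit_homogeneous_io(group_encoded, group_trees, model_names)
    # shared model parameters are counted once, not per group
    from .models import parameter_count

    overcount = (len(fits) - 1) * parameter_count(next(iter(fits.values())).model)
    return HypothesisFit("IO", fits, alignment.n_columns, k_correction=-overcount)


@dataclass
class SeparateAlignmentResult:
    """Fig.-4-style comparison where each hypothesis aligns its own data.

    Explicitly a cross-alignment comparison: the information criteria are
    computed on different data sets, so the scaled differences have no
    probabilistic interpretation; they are reported as descriptive
    statistics only.
    """

    group_fits: Dict[str, FitResult]
    joint_fit: FitResult
    group_columns: Dict[str, int]
    joint_columns: int

    cross_alignment_comparison: bool = True

    @property
    def scaled_delta_aic(self) -> float:
        total = sum(f.aic for f in self.group_fits.values())
        return (total - self.joint_fit.aic) / self.joint_columns

    @property
    def scaled_delta_bic(self) -> float:
        total = sum(
            bic(f.loglik, f.k, self.group_columns[g])
            for g, f in self.group_fits.items()
        )
        return (total - self.joint_fit.bic) / self.joint_columns

    @property
    def length_ratio(self) -> float:
        """Joint alignment columns over the mean separate column count."""
        return self.joint_columns / float(np.mean(list(self.group_columns.values())))


def delta_ic_separate_alignments(
    groups_unaligned: Dict[str, SequenceSet],
    model_names: Sequence[str] = DEFAULT_MODEL_SET,
    topology_model: str = DEFAULT_TOPOLOGY_MODEL,
) -> SeparateAlignmentResult:
    """Align each group alone and the pooled set jointly; compare summed
    group information criteria with the joint ones, per joint-alignment
    site.  Positive values favour common ancestry."""
    if len(groups_unaligned) < 2:
        raise ValueError("need at least two groups")
    group_fits = {}
    group_cols = {}
    pooled_records = []
    for name, seqs in groups_unaligned.items():
        seqs = strip_gaps(seqs)
        pooled_records.extend(seqs.records)
        aln = progressive_align(seqs)
        group_cols[name] = aln.n_columns
        enc = _EncodedAlignment(aln)
        group_fits[name] = _best_fit_on_shared_topology(enc, model_names, topology_model)
    joint_aln = progressive_align(SequenceSet(pooled_records))
    joint_fit = _best_fit_on_shared_topology(
        _EncodedAlignment(joint_aln), model_names, topology_model
    )
    return SeparateAlignmentResult(
        group_fits, joint_fit, group_cols, joint_aln.n_columns
    )


# -- statsmodels-style front door --------------------------------------


class CommonAncestryTest:
    """Model-selection test of common ancestry, built from data.

    Parameters
    ----------
    alignment : SequenceSet
        Aligned sequences (the shared data both hypotheses are scored on).
    partition : Partition or dict
        Grouping of identifiers into putative independent origins.
    model_names : sequence of str
        Candidate substitution models for both hypotheses.
    separate_alignments : bool
        Use the cross-alignment variant (each group aligned alone); the
        input may then be unaligned.
    force_homogeneous : bool
        Share one substitution model across IO groups.

    ``fit()`` returns a :class:`CommonAncestryResults`.
    """

    def __init__(
        self,
        alignment: SequenceSet,
        partition: Partition | Dict,
        model_names: Sequence[str] = DEFAULT_MODEL_SET,
        separate_alignments: bool = False,
        force_homogeneous: bool = False,
        topology_model: str = DEFAULT_TOPOLOGY_MODEL,
    ):
        self.alignment = alignment
        self.partition = as_partition(partition)
        self.model_names = tuple(model_names)
        self.separate_alignments = separate_alignments
        self.force_homogeneous = force_homogeneous
        self.topology_model = topology_model

    @classmethod
    def from_files(cls, fasta_path, groups_path, **kwargs) -> "CommonAncestryTest":
        from .io_formats import read_fasta

        return cls(read_fasta(fasta_path), Partition.from_yaml(groups_path), **kwargs)

    def fit(self) -> "CommonAncestryResults":
        if self.separate_alignments:
            groups = {
                name: self.alignment.subset(self.partition.members(name))
                for name in self.partition.names
            }
            sep = delta_ic_separate_alignments(
                groups, self.model_names, self.topology_model
            )
            return CommonAncestryResults(model=self, separate=sep)
        res = delta_aic_test(
            self.alignment,
            self.partition,
            self.model_names,
            self.topology_model,
            self.force_homogeneous,
        )
        return CommonAncestryResults(model=self, shared=res)


@dataclass
class CommonAncestryResults:
    """Results wrapper with ``summary()`` and ``to_dict()``."""

    model: CommonAncestryTest
    shared: Optional[UcaTestResult] = None
    separate: Optional[SeparateAlignmentResult] = None

    @property
    def delta_aic(self) -> float:
        if self.shared is not None:
            return self.shared.delta_aic
        return self.separate.scaled_delta_aic * self.separate.joint_columns

    @property
    def classification(self) -> str:
        if self.shared is not None:
            return self.shared.classification
        return _classify(self.separate.scaled_delta_aic)

    def summary(self) -> str:
        if self.shared is not None:
            return self.shared.summary()
        s = self.separate
        lines = [
            "Common-ancestry test with separately optimised alignments",
            "=" * 60,
            f"joint alignment columns:     {s.joint_columns}",
            f"separate alignment columns:  "
            + ", ".join(f"{g}={n}" for g, n in s.group_columns.items()),
            f"length ratio (joint/mean separate): {s.length_ratio:.4f}",
            f"scaled delta_AIC per joint site:    {s.scaled_delta_aic:.5f}",
            f"scaled delta_BIC per joint site:    {s.scaled_delta_bic:.5f}",
            "note: cross-alignment comparison - no probabilistic interpretation",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        if self.shared is not None:
            payload = self.shared.to_dict()
        else:
            s = self.separate
            payload = {
                "scaled_delta_aic": s.scaled_delta_aic,
                "scaled_delta_bic": s.scaled_delta_bic,
                "length_ratio": s.length_ratio,
                "joint_columns": s.joint_columns,
                "group_columns": s.group_columns,
                "cross_alignment_comparison": True,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
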