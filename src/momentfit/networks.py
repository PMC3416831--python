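"""Stochastic reaction networks and the built-in test models.

A well-mixed network of ``v`` reactions over ``u`` species is characterized by
its stoichiometric matrix ``S`` (u x v, net copy-number change per firing) and
a family of propensity (hazard) functions ``h_j(x, c) >= 0`` giving the rate of
reaction ``j`` in state ``x`` under the rate-parameter vector ``c``.
Propensities are held as sympy expressions so that every downstream consumer
(SSA, moment ODE systems, adjoint sensitivities) can derive exact numeric or
symbolic forms from one definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import sympy as sp

from .errors import ValidationError

__all__ = [
    "ReactionNetwork",
    "ObservationOperator",
    "make_network",
    "builtin_model",
    "propensities",
    "equidistant_times",
    "BUILTIN_MODELS",
]


def _classify(expr, x_syms):
    """Classify a propensity as affine, polynomial or rational in the state."""
    expr = sp.together(sp.expand(expr))
    num, den = sp.fraction(expr)
    if den.free_symbols & set(x_syms):
        return "rational"
    if not num.is_polynomial(*x_syms):
        return "rational"
    deg = sp.total_degree(sp.Poly(num, *x_syms)) if x_syms else 0
    return "affine" if deg <= 1 else "polynomial"


class ReactionNetwork:
    """Species, stoichiometry, symbolic propensities and rate parameters."""

    def __init__(self, species_names, param_names, stoich, propensity_exprs,
                 x0, default_params=None, name=None, reaction_names=None):
        self.species_names = list(species_names)
        self.param_names = list(param_names)
        self.n_species = len(self.species_names)
        self.n_params = len(self.param_names)
        self.name = name
        self.stoich = np.asarray(stoich, dtype=int)
        if self.stoich.shape[0] != self.n_species:
            raise ValidationError(
                f"stoichiometric matrix has {self.stoich.shape[0]} rows "
                f"for {self.n_species} species")
        self.n_reactions = self.stoich.shape[1]
        if len(propensity_exprs) != self.n_reactions:
            raise ValidationError("one propensity per stoichiometry column required")
        self.x_syms = sp.symbols([f"__x_{s}" for s in self.species_names],
                                 nonnegative=True)
        self.c_syms = sp.symbols([f"__c_{p}" for p in self.param_names],
                                 positive=True)
        # expressions arrive in symbols named after species / params
        local = {s: xs for s, xs in zip(self.species_names, self.x_syms)}
        local.update({p: cs for p, cs in zip(self.param_names, self.c_syms)})
        self.propensity_exprs = []
        for j, e in enumerate(propensity_exprs):
            expr = sp.sympify(e, locals=local) if not isinstance(e, sp.Expr) else e
            extra = expr.free_symbols - set(self.x_syms) - set(self.c_syms)
            if extra:
                raise ValidationError(
                    f"reaction {self._rname(reaction_names, j)}: unknown symbols {extra}")
            self.propensity_exprs.append(expr)
        self.reaction_names = (list(reaction_names) if reaction_names
                               else [f"R{j+1}" for j in range(self.n_reactions)])
        self.propensity_kind = [_classify(e, self.x_syms)
                                for e in self.propensity_exprs]
        self.x0 = np.asarray(x0, dtype=int)
        if self.x0.shape != (self.n_species,) or np.any(self.x0 < 0):
            raise ValidationError("x0 must be a non-negative integer vector, one entry per species")
        if default_params is not None:
            default_params = np.asarray(default_params, dtype=float)
            if default_params.shape != (self.n_params,) or np.any(default_params <= 0):
                raise ValidationError("default_params must be positive, one per parameter")
        self.default_params = default_params
        self._h_numpy = sp.lambdify((self.x_syms, self.c_syms),
                                    [sp.Float(0) + e for e in self.propensity_exprs],
                                    "numpy")
        self._cache = {}

    @staticmethod
    def _rname(reaction_names, j):
        return reaction_names[j] if reaction_names else f"R{j+1}"

    def propensities(self, x, c):
        """Evaluate h(x, c); domain error for negative state or parameters."""
        x = np.asarray(x, dtype=float)
        c = np.asarray(c, dtype=float)
        if x.shape != (self.n_species,) or np.any(x < 0):
            raise ValidationError("state must be non-negative, one entry per species")
        if c.shape != (self.n_params,) or np.any(c < 0):
            raise ValidationError("rate parameters must be non-negative")
        h = np.asarray(self._h_numpy(tuple(x), tuple(c)), dtype=float)
        if not np.all(np.isfinite(h)) or np.any(h < -1e-12):
            bad = self.reaction_names[int(np.argmin(h))]
            raise ValidationError(f"propensity of reaction {bad} is negative or non-finite")
        return np.maximum(h, 0.0)

    def propensity_fn(self, c):
        """Fast scalar evaluator ``h(*x) -> list`` with parameters bound.

        Used in the inner SSA loop; one python call per jump event.
        """
        c = np.asarray(c, dtype=float)
        if c.shape != (self.n_params,) or np.any(c < 0):
            raise ValidationError("rate parameters must be non-negative")
        subs = dict(zip(self.c_syms, [sp.Float(v) for v in c]))
        exprs = [e.subs(subs) for e in self.propensity_exprs]
        return sp.lambdify(self.x_syms, exprs, "math")

    def __repr__(self):
        return (f"ReactionNetwork({self.name or 'custom'}: "
                f"{self.n_species} species, {self.n_reactions} reactions, "
                f"{self.n_params} parameters)")


@dataclass(frozen=True)
class ObservationOperator:
    """Partial observation: which species are seen, and at which times."""

    observed_indices: tuple
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "observed_indices",
                           tuple(int(i) for i in self.observed_indices))
        object.__setattr__(self, "times",
                           np.asarray(self.times, dtype=float))
        if len(set(self.observed_indices)) != len(self.observed_indices):
            raise ValidationError("observed indices must be distinct")
        if len(self.observed_indices) == 0:
            raise ValidationError("at least one observed species required")
        t = self.times
        if t.ndim != 1 or len(t) < 1:
            raise ValidationError("at least one observation time required")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("observation times must be non-negative and strictly increasing")

    @property
    def K(self):
        return len(self.times)

    @property
    def d(self):
        return len(self.observed_indices)


def equidistant_times(t_end, k):
    """K observation times t_i = i * (T/K), i = 1..K (t_1 > 0)."""
    if t_end <= 0 or k < 1:
        raise ValidationError("t_end > 0 and k >= 1 required")
    dt = t_end / k
    return dt * np.arange(1, k + 1)


def _mass_action_expr(reactants, species_names, rate_sym, local):
    """Stochastic mass-action law: c * prod_s binom(x_s, r_s) falling factorials."""
    expr = rate_sym
    for s, r in reactants.items():
        xs = local[s]
        for i in range(r):
            expr = expr * (xs - i)
        expr = expr / math.factorial(r)
    return expr


def make_network(spec):
    """Build a validated :class:`ReactionNetwork` from a structured description.

    ``spec`` is a mapping with keys ``species`` (names), ``reactions`` (each
    with ``reactants``/``products`` count mappings and either
    ``law: mass_action`` + ``rate_param`` or ``law: expression`` + ``expr``),
    ``params`` (list of names or name -> default value mapping), ``x0`` and
    optional ``constants`` (fixed model constants substituted into
    expressions) and ``name``.
    """
    try:
        species = list(spec["species"])
        reactions = list(spec["reactions"])
        params = spec["params"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"network spec missing required key: {exc}") from exc
    if isinstance(params, dict):
        param_names = list(params.keys())
        defaults = np.asarray([params[p] for p in param_names], dtype=float)
    else:
        param_names = list(params)
        defaults = None
    constants = dict(spec.get("constants", {}))
    local = {s: sp.Symbol(s, nonnegative=True) for s in species}
    local.update({p: sp.Symbol(p, positive=True) for p in param_names})

    stoich = np.zeros((len(species), len(reactions)), dtype=int)
    exprs, names = [], []
    for j, rx in enumerate(reactions):
        rname = rx.get("name", f"R{j+1}")
        names.append(rname)
        reactants = dict(rx.get("reactants", {}))
        products = dict(rx.get("products", {}))
        for side, counts in (("reactant", reactants), ("product", products)):
            for s, cnt in counts.items():
                if s not in local or s in param_names:
                    raise ValidationError(f"reaction {rname}: unknown species '{s}'")
                if not isinstance(cnt, int) or cnt < 0:
                    raise ValidationError(
                        f"reaction {rname}: {side} count for '{s}' must be a non-negative integer")
        for s, cnt in reactants.items():
            stoich[species.index(s), j] -= cnt
        for s, cnt in products.items():
            stoich[species.index(s), j] += cnt
        law = rx.get("law", "mass_action")
        if law == "mass_action":
            rp = rx.get("rate_param")
            if rp not in param_names:
                raise ValidationError(f"reaction {rname}: rate_param '{rp}' not in params")
            exprs.append(_mass_action_expr(reactants, species, local[rp], local))
        elif law == "expression":
            try:
                e = sp.sympify(rx["expr"], locals=local)
            except (sp.SympifyError, KeyError) as exc:
                raise ValidationError(f"reaction {rname}: invalid expression ({exc})") from exc
            e = e.subs({sp.Symbol(k, positive=True): v for k, v in constants.items()})
            e = e.subs({sp.Symbol(k): v for k, v in constants.items()})
            extra = e.free_symbols - set(local.values())
            if extra:
                raise ValidationError(f"reaction {rname}: unknown symbols {extra}")
            exprs.append(e)
        else:
            raise ValidationError(f"reaction {rname}: unknown propensity law '{law}'")
    x0 = spec.get("x0", np.zeros(len(species), dtype=int))
    # re-express in plain name symbols for the ReactionNetwork constructor
    exprs = [str(e) for e in exprs]
    return ReactionNetwork(species, param_names, stoich, exprs, x0,
                           default_params=defaults, name=spec.get("name"),
                           reaction_names=names)


def _birth_death():
    return make_network({
        "name": "birth_death",
        "species": ["X"],
        "params": {"c1": 0.1, "c2": 0.2},
        "x0": [30],
        "reactions": [
            {"name": "birth", "reactants": {"X": 1}, "products": {"X": 2},
             "law": "mass_action", "rate_param": "c1"},
            {"name": "death", "reactants": {"X": 1}, "products": {},
             "law": "mass_action", "rate_param": "c2"},
        ],
    })


def _dimerisation(total=301):
    # Conservation x + 2*dimers = M reduces the two-species system to the
    # monomer count x alone: dimerise 2X -> D has net change -2 with
    # h1 = c1*x*(x-1)/2, dissociate D -> 2X has net change +2 with
    # h2 = c2*(M-x)/2.  M is a model constant, not a fitted parameter.
    return make_network({
        "name": "dimerisation",
        "species": ["X"],
        "params": {"c1": 1.66e-3, "c2": 0.2},
        "constants": {"M": total},
        "x0": [total],
        "reactions": [
            {"name": "dimerise", "reactants": {"X": 2}, "products": {},
             "law": "mass_action", "rate_param": "c1"},
            {"name": "dissociate", "reactants": {}, "products": {"X": 2},
             "law": "expression", "expr": f"c2*(M - X)/2"},
        ],
    })


def _p53():
    # Feedback loop between p53 (x), the Mdm2 precursor (y0) and Mdm2 (y):
    # constitutive p53 production, basal p53 degradation, Mdm2-mediated p53
    # degradation with a saturating (rational) rate a_k*y*x/(x+k), p53-driven
    # precursor production, precursor maturation, Mdm2 degradation.  The
    # default rates put the loop in the damped-oscillation regime that is the
    # hallmark of the real p53/Mdm2 system (hours time scale, basal
    # degradation much slower than Mdm2-mediated degradation).
    return make_network({
        "name": "p53",
        "species": ["p53", "mdm2_prec", "mdm2"],
        "params": {"b_x": 90.0, "a_x": 0.02, "a_k": 2.0, "k": 30.0,
                   "b_y": 0.2, "a_0": 0.5, "a_y": 0.5},
        "x0": [20, 5, 10],
        "reactions": [
            {"name": "p53_production", "reactants": {}, "products": {"p53": 1},
             "law": "expression", "expr": "b_x"},
            {"name": "p53_degradation", "reactants": {"p53": 1}, "products": {},
             "law": "mass_action", "rate_param": "a_x"},
            {"name": "p53_mdm2_degradation", "reactants": {"p53": 1}, "products": {},
             "law": "expression", "expr": "a_k*mdm2*p53/(p53 + k)"},
            {"name": "prec_production", "reactants": {}, "products": {"mdm2_prec": 1},
             "law": "expression", "expr": "b_y*p53"},
            {"name": "maturation", "reactants": {"mdm2_prec": 1}, "products": {"mdm2": 1},
             "law": "mass_action", "rate_param": "a_0"},
            {"name": "mdm2_degradation", "reactants": {"mdm2": 1}, "products": {},
             "law": "mass_action", "rate_param": "a_y"},
        ],
    })


BUILTIN_MODELS = {
    "birth_death": _birth_death,
    "dimerisation": _dimerisation,
    "p53": _p53,
}


def builtin_model(name, **kwargs):
    """Return one of the built-in test networks by name."""
    try:
        factory = BUILTIN_MODELS[name]
    except KeyError:
        raise ValidationError(
            f"unknown model '{name}'; available: {sorted(BUILTIN_MODELS)}") from None
    return factory(**kwargs)


def propensities(net, x, c):
    """Module-level alias for :meth:`ReactionNetwork.propensities`."""
    return net.propensities(x, c)
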