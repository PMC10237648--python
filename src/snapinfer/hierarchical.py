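"""Traditional hierarchical NLME log-likelihood and posterior.

The hierarchical log-likelihood of population parameters ``theta`` and
per-individual parameters ``Psi = (psi_1, ..., psi_N)`` is

    log p(D, Psi | theta) = sum_ij log p(y_ij | psi_i, t_j)
                          + sum_i  log p(psi_i | theta),

with missing measurements contributing nothing.  Evaluating it requires one
time-series model evaluation per measured individual, so the cost grows
linearly with N — the bottleneck that filter inference removes.

``HierarchicalPosterior`` exposes the posterior (likelihood plus a prior on
theta) with analytic gradients on an unconstrained scale, ready for NUTS.
"""

from __future__ import annotations

import numpy as np

from .dataset import SnapshotDataset
from .layout import ThetaLayout, TransformedBlock
from .models import NLMEModel

__all__ = ["HierarchicalPosterior", "hierarchical_loglik"]


class HierarchicalPosterior:
    """Joint posterior over (theta, Psi) for a snapshot dataset.

    Parameters
    ----------
    data
        Snapshot dataset; every individual contributes one psi vector.
    model
        NLME model bundle.
    prior
        ``PriorSpec`` covering every free theta dimension; ``None`` means flat
        (improper) priors everywhere.
    fixed
        Mapping of theta names to pinned values, excluded from sampling.
    """

    def __init__(self, data: SnapshotDataset, model: NLMEModel, prior=None,
                 fixed=None):
        self.data = data
        self.model = model
        self.prior = prior
        pop = model.population
        self.theta = ThetaLayout(pop, fixed)
        if prior is not None:
            missing = [n for n in self.theta.free_names if n not in prior]
            if missing:
                raise KeyError(f"prior is missing parameters {missing}")
        self.free_psi = pop.free_psi_dims
        self.psi_block = TransformedBlock(pop.psi_transforms())
        self.n_psi_free = len(self.free_psi)
        self.ids = data.individual_ids
        self.N = len(self.ids)
        self.times = data.times
        self.observables = data.observables
        if model.time_series.n_observables != len(self.observables):
            # datasets may observe a subset; map names to output indices
            pass
        self.covariates = data.covariates() if pop.requires_covariates() else None
        self._index_data()
        # mechanistic dims whose sensitivities are needed
        mech_free = [k for k in self.free_psi if k < model.n_mech]
        mech_pm = [k for k, j in pop.point_mass_map
                   if k < model.n_mech and pop.theta_names[j] not in
                   self.theta.fixed]
        self.sens_dims = sorted(set(mech_free) | set(mech_pm))
        from .priors import IDENTITY
        self._all_psi_identity = all(
            t is IDENTITY for t in self.psi_block.transforms)

    def _index_data(self):
        """Group individuals by their set of measured (time, observable) cells."""
        from .models import observable_map

        frame = self.data.frame
        times = self.times
        obs_index = observable_map(self.model.time_series, self.observables)
        per_id = {}
        for _, row in frame.iterrows():
            j = int(np.searchsorted(times, row["Time"]))
            per_id.setdefault(row["ID"], []).append(
                (j, obs_index[row["Observable"]], row["Value"]))
        groups = {}
        for i, id_ in enumerate(self.ids):
            cells = sorted(per_id[id_])
            tkey = tuple(sorted({j for j, _, _ in cells}))
            groups.setdefault(tkey, []).append((i, cells))
        # per group: individual indices, local time array, cell index arrays
        self._groups = []
        for tkey, members in groups.items():
            t_local = times[list(tkey)]
            remap = {j: a for a, j in enumerate(tkey)}
            idx = np.array([i for i, _ in members])
            rows, jj, oo, vals = [], [], [], []
            for r, (_, cells) in enumerate(members):
                for j, o, v in cells:
                    rows.append(r)
                    jj.append(remap[j])
                    oo.append(o)
                    vals.append(v)
            self._groups.append((
                idx, t_local, np.array(rows), np.array(jj), np.array(oo),
                np.array(vals, float)))

    # -- layout ------------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return self.theta.n_free + self.N * self.n_psi_free

    @property
    def parameter_names(self):
        names = list(self.theta.free_names)
        psi_names = [self.model.population.psi_names[k] for k in self.free_psi]
        for id_ in self.ids:
            names.extend(f"psi_{p}[{id_}]" for p in psi_names)
        return names

    def pack(self, theta_full, Psi):
        """Natural-scale (theta, Psi (N, n_psi)) -> unconstrained vector."""
        x_theta = self.theta.to_unconstrained(theta_full)
        Psi = np.atleast_2d(np.asarray(Psi, float))
        x_psi = np.stack([
            self.psi_block.to_unconstrained(Psi[i, self.free_psi])
            for i in range(self.N)])
        return np.concatenate([x_theta, x_psi.ravel()])

    def unpack(self, x):
        x = np.asarray(x, float)
        theta = self.theta.to_natural(x[: self.theta.n_free])
        xp = x[self.theta.n_free:].reshape(self.N, self.n_psi_free)
        Psi = np.zeros((self.N, self.model.population.n_psi))
        if self._all_psi_identity:
            Psi[:, self.free_psi] = xp
        else:
            for i in range(self.N):
                Psi[i, self.free_psi] = self.psi_block.to_natural(xp[i])
        Psi = self.model.population.fill_point_masses(Psi, theta)
        return theta, Psi

    def sample_initial(self, rng, theta=None):
        """Ancestral starting point: theta from the prior, psi_i | theta."""
        if theta is None:
            if self.prior is None:
                raise ValueError("need a proper prior or an explicit theta")
            free = self.prior.sample(self.theta.free_names, rng)
            theta = self.theta.full_theta(free)
        Psi = self.model.population.sample(theta, self.N, rng, self.covariates)
        return self.pack(theta, Psi)

    # -- evaluation --------------------------------------------------------
    def loglik(self, theta, Psi):
        """Natural-scale hierarchical log-likelihood (no prior, no Jacobian)."""
        value, _, _ = self._loglik_grads(np.asarray(theta, float),
                                         np.atleast_2d(np.asarray(Psi, float)))
        return value

    def _loglik_grads(self, theta, Psi):
        pop = self.model.population
        model = self.model
        error = model.error
        value = 0.0
        dtheta = np.zeros(pop.n_theta)
        dPsi = np.zeros_like(Psi)
        # population term
        lp, dpsi_pop, dtheta_pop = pop.logpdf_grads(Psi, theta, self.covariates)
        value += lp.sum()
        dPsi += dpsi_pop
        dtheta += dtheta_pop.sum(axis=0)
        # error term, one trajectory per individual
        sigma = Psi[:, model.n_mech]
        for idx, t_local, rows, jj, oo, vals in self._groups:
            mech = Psi[idx, : model.n_mech]
            ybar, sens = model.time_series.simulate_batch_with_sensitivities(
                mech, t_local, wrt=self.sens_dims)
            yb = ybar[rows, jj, oo]
            if not np.all(error.in_support(vals, yb)):
                return -np.inf, dtheta, dPsi
            lp, _, dybar, dsigma = error.logpdf_grads(vals, yb, sigma[idx][rows])
            value += lp.sum()
            # d/d mech params through sensitivities
            sens_cells = sens[rows, jj, oo, :]          # (cells, n_sens)
            contrib = dybar[:, None] * sens_cells
            for a, k in enumerate(self.sens_dims):
                np.add.at(dPsi[:, k], idx[rows], contrib[:, a])
            np.add.at(dPsi[:, model.n_mech], idx[rows], dsigma)
        # point-mass psi dims are theta values: move their gradient to theta
        for k, j in pop.point_mass_map:
            dtheta[j] += dPsi[:, k].sum()
        return value, dtheta, dPsi

    def __call__(self, x):
        return self.evaluate(x)[0]

    def evaluate(self, x):
        """Unconstrained log-posterior and gradient (prior + Jacobians included)."""
        # overflow in extreme proposals ends in the -inf rejection path
        with np.errstate(over="ignore", invalid="ignore"):
            return self._evaluate(x)

    def _evaluate(self, x):
        x = np.asarray(x, float)
        grad = np.zeros_like(x)
        theta, Psi = self.unpack(x)
        theta_free = self.theta.free_of(theta)
        # prior (theta outside support -> -inf, not an exception)
        prior_lp, prior_grad = 0.0, np.zeros(self.theta.n_free)
        if self.prior is not None:
            for a, name in enumerate(self.theta.free_names):
                dist = self.prior[name]
                if not dist.in_support(theta_free[a]):
                    return -np.inf, grad
                prior_lp += dist.logpdf(theta_free[a])
                prior_grad[a] = dist.dlogpdf(theta_free[a])
        value, dtheta, dPsi = self._loglik_grads(theta, Psi)
        if not np.isfinite(value):
            return -np.inf, grad
        # chain rule through transforms plus log-Jacobians
        nt = self.theta.n_free
        x_theta = x[:nt]
        grad[:nt] = (dtheta[self.theta.free_idx] + prior_grad) \
            * self.theta.block.dnatural(x_theta) \
            + self.theta.block.dlog_jacobian(x_theta)
        value += prior_lp + self.theta.block.log_jacobian(x_theta)
        xp = x[nt:].reshape(self.N, self.n_psi_free)
        if self._all_psi_identity:
            grad[nt:] = dPsi[:, self.free_psi].ravel()
        else:
            gpsi = np.empty_like(xp)
            for i in range(self.N):
                gpsi[i] = dPsi[i, self.free_psi] \
                    * self.psi_block.dnatural(xp[i]) \
                    + self.psi_block.dlog_jacobian(xp[i])
                value += self.psi_block.log_jacobian(xp[i])
            grad[nt:] = gpsi.ravel()
        return value, grad


def hierarchical_loglik(data: SnapshotDataset, theta, Psi, model: NLMEModel):
    """Convenience wrapper: natural-scale hierarchical log-likelihood."""
    post = HierarchicalPosterior(data, model)
    return post.loglik(theta, Psi)
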