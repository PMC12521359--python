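"""Convolutional variational deep embedding with a Gaussian-mixture prior.

The generative model is ``p(x, z, c) = p(x | z) p(z | c) p(c)``: a
categorical cluster assignment ``c``, a cluster-specific diagonal Gaussian
latent ``z``, and a Poisson (or Bernoulli) observation model over the band
image decoded from ``z``.  The encoder/decoder are convolutional: four
blocks of two 3x3 convolutions, the last layer of each encoder block with
stride 2 along the genome axis (filters 4, 8, 16, 32), mirrored by
upsample+convolution blocks in the decoder (32, 16, 8, 4) and a final 1x1
convolution onto the output distribution parameters.

Training maximizes the evidence lower bound: reconstruction log-likelihood
minus the KL divergence between the amortized posterior ``q(z, c | x)`` and
the mixture prior, with ``q(c | x)`` computed from the posterior mean of
``q(z | x)`` by Bayes' rule under the current mixture.  A reconstruction-only
warm-up (first 40% of epochs by default) precedes initializing the mixture by
fitting a Gaussian mixture to the warm latents; the mixture parameters then
train with their own, larger Adam step so that surplus components consolidate
within the training budget.  With one unit-variance component the bound
reduces to the standard VAE ELBO.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .nn import (Adam, Conv2D, Dense, Flatten, Param, ReLU, Reshape,
                 Sequential, Upsample, sigmoid, softplus)

__all__ = ["MixturePrior", "ConvGMVAE", "Va3DE", "elbo"]

_RATE_FLOOR = 1e-6


@dataclass
class MixturePrior:
    """Mixture weights and per-component diagonal Gaussians in latent space."""

    weights: np.ndarray   # (C,), simplex
    means: np.ndarray     # (C, d_z)
    variances: np.ndarray  # (C, d_z), > 0


def _log_softmax(x: np.ndarray) -> np.ndarray:
    return x - logsumexp(x)


class ConvGMVAE:
    """Network + mixture parameters; all state lives in ``Param`` objects."""

    ENC_FILTERS = (4, 8, 16, 32)
    DEC_FILTERS = (32, 16, 8, 4)

    def __init__(self, input_shape: tuple[int, int], latent_dim: int,
                 n_components: int, likelihood: str = "poisson",
                 rng: np.random.Generator | None = None):
        if likelihood not in ("poisson", "bernoulli"):
            raise ValueError("likelihood must be 'poisson' or 'bernoulli'")
        rng = rng or np.random.default_rng(0)
        self.input_shape = tuple(input_shape)
        self.latent_dim = latent_dim
        self.n_components = n_components
        self.likelihood = likelihood

        k, width = input_shape
        # block-end stride 2 along both axes while the strata axis allows it
        shapes = [(k, width)]
        strides = []
        enc_layers: list = []
        in_ch = 1
        for f in self.ENC_FILTERS:
            h, w = shapes[-1]
            stride = (2 if h >= 4 else 1, 2)
            strides.append(stride)
            enc_layers += [Conv2D(in_ch, f, 3, (1, 1), rng=rng), ReLU(),
                           Conv2D(f, f, 3, stride, rng=rng), ReLU()]
            shapes.append(((h - 1) // stride[0] + 1, (w - 1) // stride[1] + 1))
            in_ch = f
        self._shapes = shapes  # shapes[0]=input, shapes[-1]=deepest
        feat = self.ENC_FILTERS[-1] * shapes[-1][0] * shapes[-1][1]
        enc_layers += [Flatten(), Dense(feat, 2 * latent_dim, rng=rng)]
        self.encoder = Sequential(*enc_layers)

        dec_layers: list = [Dense(latent_dim, feat, rng=rng),
                            Reshape((*shapes[-1], self.ENC_FILTERS[-1])),
                            ReLU()]
        in_ch = self.ENC_FILTERS[-1]
        for f, target, stride in zip(self.DEC_FILTERS, shapes[-2::-1],
                                     strides[::-1]):
            dec_layers += [Upsample(stride, target),
                           Conv2D(in_ch, f, 3, (1, 1), rng=rng), ReLU(),
                           Conv2D(f, f, 3, (1, 1), rng=rng), ReLU()]
            in_ch = f
        dec_layers += [Conv2D(in_ch, 1, 1, (1, 1), pad=0, rng=rng)]
        self.decoder = Sequential(*dec_layers)

        self.mean_total: float | None = None  # reference library size
        self.pi_logits = Param(np.zeros(n_components), "prior.pi")
        self.mu_c = Param(rng.normal(0, 0.1, size=(n_components, latent_dim)),
                          "prior.mu")
        self.logvar_c = Param(np.zeros((n_components, latent_dim)), "prior.logvar")

    # -- parameter groups ---------------------------------------------------
    def net_params(self) -> list[Param]:
        return self.encoder.params() + self.decoder.params()

    def prior_params(self) -> list[Param]:
        return [self.pi_logits, self.mu_c, self.logvar_c]

    def prior(self) -> MixturePrior:
        w = np.exp(_log_softmax(self.pi_logits.value))
        return MixturePrior(w, self.mu_c.value.copy(),
                            np.exp(self.logvar_c.value))

    def set_prior(self, weights, means, variances) -> None:
        self.pi_logits.value = np.log(np.clip(weights, 1e-12, None))
        self.mu_c.value = np.asarray(means, dtype=float).copy()
        self.logvar_c.value = np.log(np.clip(variances, 1e-8, None))

    # -- forward passes -----------------------------------------------------
    def exposure(self, x: np.ndarray) -> np.ndarray:
        """Per-cell library-size factor relative to the reference depth.

        Sequencing depth is a nuisance axis: the encoder sees depth-normalized
        images while the Poisson rate is rescaled back per cell, so the latent
        space is free to encode structure rather than coverage.
        """
        totals = x.sum(axis=(1, 2))
        if self.mean_total is None:
            self.mean_total = float(totals.mean())
        return np.maximum(totals, 1.0) / self.mean_total

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = self.exposure(x)[:, None, None]
        h = self.encoder.forward(np.log1p(x / e).astype(np.float32)[..., None])
        return h[:, :self.latent_dim], h[:, self.latent_dim:]

    def decode(self, z: np.ndarray, exposure: np.ndarray | None = None) -> np.ndarray:
        logits = self.decoder.forward(z)[..., 0]
        if self.likelihood == "poisson":
            rate = softplus(logits) + _RATE_FLOOR
            if exposure is not None:
                rate = rate * exposure[:, None, None]
            return rate
        return sigmoid(logits)

    def responsibilities(self, z: np.ndarray) -> np.ndarray:
        """Posterior q(c | z) under the mixture prior, rows summing to 1."""
        log_pi = _log_softmax(self.pi_logits.value)
        var_c = np.exp(self.logvar_c.value)
        # (N, C): log pi_c + log N(z; mu_c, var_c)
        diff = z[:, None, :] - self.mu_c.value[None]
        log_n = -0.5 * (np.log(2 * np.pi) + self.logvar_c.value[None]
                        + diff ** 2 / var_c[None]).sum(axis=2)
        logits = log_pi[None] + log_n
        logits -= logits.max(axis=1, keepdims=True)
        g = np.exp(logits)
        return g / g.sum(axis=1, keepdims=True)

    # -- likelihood ---------------------------------------------------------
    def nll(self, x: np.ndarray, out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell negative log-likelihood and its gradient wrt the output."""
        x = np.asarray(x, dtype=np.float64)
        out = np.asarray(out, dtype=np.float64)
        if self.likelihood == "poisson":
            per = (out - x * np.log(out) + gammaln(x + 1.0)).sum(axis=(1, 2))
            grad = 1.0 - x / out
        else:
            p = np.clip(out, 1e-7, 1 - 1e-7)
            xb = (x > 0).astype(float)
            per = -(xb * np.log(p) + (1 - xb) * np.log(1 - p)).sum(axis=(1, 2))
            grad = (p - xb) / (p * (1 - p))
        return per, grad

    # -- ELBO ---------------------------------------------------------------
    def elbo_terms(self, x: np.ndarray, eps: np.ndarray | None = None) -> dict:
        """Per-batch ELBO decomposition (means over cells); no gradients."""
        mu, logvar = self.encode(x)
        z = mu if eps is None else mu + eps * np.exp(0.5 * logvar)
        out = self.decode(z, self.exposure(x))
        per_nll, _ = self.nll(x, out)
        kl_z, kl_c = self._kl_terms(mu, logvar)
        nll = float(per_nll.mean())
        kl = float((kl_z + kl_c).mean())
        for name, val in (("nll", nll), ("kl", kl)):
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite ELBO term: {name}")
        return {"nll": nll, "kl": kl, "loss": nll + kl, "elbo": -(nll + kl),
                "mu": mu, "logvar": logvar}

    def _kl_terms(self, mu: np.ndarray, logvar: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        mu = np.asarray(mu, dtype=np.float64)
        logvar = np.asarray(logvar, dtype=np.float64)
        gamma = self.responsibilities(mu)
        var = np.exp(logvar)
        var_c = np.exp(self.logvar_c.value)
        diff = mu[:, None, :] - self.mu_c.value[None]
        kl_z_per_c = 0.5 * (self.logvar_c.value[None] - logvar[:, None, :]
                            + (var[:, None, :] + diff ** 2) / var_c[None]
                            - 1.0).sum(axis=2)
        kl_z = (gamma * kl_z_per_c).sum(axis=1)
        log_pi = _log_softmax(self.pi_logits.value)
        kl_c = (gamma * (np.log(np.clip(gamma, 1e-12, None)) - log_pi[None])
                ).sum(axis=1)
        return kl_z, kl_c

    # -- one SGD step -------------------------------------------------------
    def step(self, x: np.ndarray, opt_net: Adam, opt_prior: Adam | None,
             rng: np.random.Generator, warmup: bool) -> dict:
        n = x.shape[0]
        e = self.exposure(x)
        mu, logvar = self.encode(x)
        if warmup:
            z = mu
            eps = None
        else:
            eps = rng.standard_normal(mu.shape).astype(mu.dtype)
            z = mu + eps * np.exp(0.5 * logvar)
        logits = self.decoder.forward(z)
        raw = logits[..., 0]
        if self.likelihood == "poisson":
            unit = softplus(raw) + _RATE_FLOOR
            out = unit * e[:, None, None]
        else:
            out = sigmoid(raw)
        per_nll, grad_out = self.nll(x, out)
        nll = float(per_nll.mean())
        # d out / d raw
        if self.likelihood == "poisson":
            draw = grad_out * e[:, None, None] * sigmoid(raw)
        else:
            draw = grad_out * out * (1.0 - out)
        opt_net.zero_grad()
        if opt_prior is not None:
            opt_prior.zero_grad()
        dz = self.decoder.backward((draw / n)[..., None].astype(mu.dtype))
        dmu = dz.copy()
        dlogvar = np.zeros_like(logvar)
        if eps is not None:
            dlogvar += 0.5 * dz * eps * np.exp(0.5 * logvar)

        kl = 0.0
        if not warmup:
            mu64 = mu.astype(np.float64)
            gamma = self.responsibilities(mu64)
            var = np.exp(logvar.astype(np.float64))
            var_c = np.exp(self.logvar_c.value)
            diff = mu64[:, None, :] - self.mu_c.value[None]
            kl_z, kl_c = self._kl_terms(mu, logvar)
            kl = float((kl_z + kl_c).mean())
            # gradients at fixed responsibilities
            dmu += ((gamma[:, :, None] * diff / var_c[None]).sum(axis=1) / n
                    ).astype(dmu.dtype)
            dlogvar += (0.5 * ((gamma[:, :, None]
                                * (var[:, None, :] / var_c[None])).sum(axis=1)
                               - 1.0) / n).astype(dlogvar.dtype)
            self.mu_c.grad += (gamma[:, :, None] * (-diff) / var_c[None]
                               ).sum(axis=0) / n
            self.logvar_c.grad += (gamma[:, :, None] * 0.5
                                   * (1.0 - (var[:, None, :] + diff ** 2)
                                      / var_c[None])).sum(axis=0) / n
            pi = np.exp(_log_softmax(self.pi_logits.value))
            self.pi_logits.grad += (pi[None] - gamma).sum(axis=0) / n
            # gradients THROUGH the responsibilities (softmax over component
            # log-joints): this is the winner-take-all pressure that empties
            # surplus mixture components as training sharpens q(c | x)
            log_pi = _log_softmax(self.pi_logits.value)
            kl_z_per_c = 0.5 * (self.logvar_c.value[None]
                                - logvar.astype(np.float64)[:, None, :]
                                + (var[:, None, :] + diff ** 2) / var_c[None]
                                - 1.0).sum(axis=2)
            b = (kl_z_per_c + np.log(np.clip(gamma, 1e-12, None))
                 - log_pi[None])
            dl = gamma * (b - (gamma * b).sum(axis=1, keepdims=True))  # (N, C)
            grad_pair = dl[:, :, None] * diff / var_c[None]
            dmu += (-grad_pair.sum(axis=1) / n).astype(dmu.dtype)
            self.mu_c.grad += grad_pair.sum(axis=0) / n
            self.logvar_c.grad += (dl[:, :, None] * (-0.5)
                                   * (1.0 - diff ** 2 / var_c[None])
                                   ).sum(axis=0) / n
            self.pi_logits.grad += dl.sum(axis=0) / n
        dh = np.concatenate([dmu, dlogvar], axis=1)
        self.encoder.backward(dh)
        loss = nll + kl
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        opt_net.step()
        if opt_prior is not None and not warmup:
            opt_prior.step()
        return {"nll": nll, "kl": kl, "loss": loss}


def elbo(images: np.ndarray, model: ConvGMVAE,
         eps: np.ndarray | None = None) -> dict:
    """Evidence-lower-bound decomposition for a batch of band images.

    Returns the mean reconstruction NLL, the KL term against the mixture
    prior, and their sum (the negative ELBO).  ``eps`` injects explicit
    reparameterization noise; ``None`` evaluates at the posterior mean.
    """
    terms = model.elbo_terms(np.asarray(images, dtype=float), eps)
    return {k: terms[k] for k in ("nll", "kl", "loss", "elbo")}


class Va3DE(BaseEstimator):
    """Convolutional Gaussian-mixture variational embedder for band images.

    Parameters mirror the published defaults (Adam, learning rate 3e-4,
    weight decay 1e-4, Poisson likelihood, encoder filters 4-8-16-32); the
    mixture is deliberately overparameterized — components that explain no
    cells have their weight pushed toward zero during training.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : posterior means of q(z | x), N x latent_dim
    responsibilities_ : posterior cluster assignment q(c | x), N x C
    prior_ : the learned :class:`MixturePrior`
    history_ : per-epoch training log (loss, nll, kl)
    """

    _stochastic = True

    def __init__(self, latent_dim: int = 10, n_components: int = 10,
                 likelihood: str = "poisson", epochs: int = 120,
                 batch_size: int = 64, learning_rate: float = 3e-4,
                 weight_decay: float = 1e-4, warmup_frac: float = 0.4,
                 prior_lr: float = 3e-2, random_state: int = 0):
        self.latent_dim = latent_dim
        self.n_components = n_components
        self.likelihood = likelihood
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.warmup_frac = warmup_frac
        self.prior_lr = prior_lr
        self.random_state = random_state

    def _encode_all(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mus, logvars = [], []
        for start in range(0, images.shape[0], self.batch_size):
            mu, lv = self.model_.encode(images[start:start + self.batch_size])
            mus.append(mu)
            logvars.append(lv)
        return np.concatenate(mus), np.concatenate(logvars)

    def fit(self, images: Sequence[np.ndarray] | np.ndarray, y=None):
        images = np.asarray(images, dtype=float)
        if images.ndim != 3:
            raise ValueError("expected an (N, k, L) band-image array")
        rng = np.random.default_rng(self.random_state)
        self.model_ = ConvGMVAE(images.shape[1:], self.latent_dim,
                                self.n_components, self.likelihood, rng)
        self.model_.mean_total = float(images.sum(axis=(1, 2)).mean())
        opt_net = Adam(self.model_.net_params(), self.learning_rate,
                       self.weight_decay)
        opt_prior = Adam(self.model_.prior_params(), self.prior_lr,
                         weight_decay=0.0)
        n = images.shape[0]
        n_warm = max(1, int(round(self.warmup_frac * self.epochs)))
        history = []
        for epoch in range(self.epochs):
            if epoch == n_warm:
                self._init_prior(images, rng)
            warmup = epoch < n_warm
            order = rng.permutation(n)
            stats = {"nll": 0.0, "kl": 0.0, "loss": 0.0}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                batch = images[order[start:start + self.batch_size]]
                try:
                    s = self.model_.step(batch, opt_net, opt_prior, rng, warmup)
                except FloatingPointError as exc:
                    raise RuntimeError(
                        f"training diverged at epoch {epoch} "
                        f"(seed {self.random_state}): {exc}") from exc
                for k in stats:
                    stats[k] += s[k]
                n_batches += 1
            history.append({"epoch": epoch,
                            **{k: v / n_batches for k, v in stats.items()},
                            "phase": "warmup" if warmup else "elbo"})
        import pandas as pd
        self.history_ = pd.DataFrame(history)
        self.history_["elbo"] = -self.history_["loss"]
        mu, _ = self._encode_all(images)
        self.embedding_ = mu
        self.responsibilities_ = self.model_.responsibilities(mu)
        self.prior_ = self.model_.prior()
        self.input_shape_ = images.shape[1:]
        return self

    def _init_prior(self, images: np.ndarray, rng: np.random.Generator) -> None:
        mu, _ = self._encode_all(images)
        gm = GaussianMixture(n_components=self.n_components,
                             covariance_type="diag", reg_covar=1e-4,
                             random_state=int(rng.integers(2 ** 31 - 1)),
                             n_init=1, max_iter=200)
        gm.fit(mu)
        self.model_.set_prior(gm.weights_, gm.means_, gm.covariances_)

    def transform(self, images: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.shape[1:] != self.input_shape_:
            raise ValueError(f"image shape {images.shape[1:]} does not match "
                             f"training shape {self.input_shape_}")
        mu, _ = self._encode_all(images)
        return mu

    def fit_transform(self, images, y=None) -> np.ndarray:
        return self.fit(images).embedding_

    def predict_proba(self, images) -> np.ndarray:
        return self.model_.responsibilities(self.transform(images))

    def save(self, path) -> None:
        """Persist all parameters and the training log to an .npz container."""
        params = (self.model_.net_params() + self.model_.prior_params())
        arrays = {f"param_{i}_{p.name}": p.value for i, p in enumerate(params)}
        np.savez(path, input_shape=np.array(self.input_shape_),
                 history=self.history_.to_records(index=False), **arrays)
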