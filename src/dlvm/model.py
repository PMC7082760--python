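"""The deep latent variable model (DLVM) for counterfactual Gleason Scores.

The model assumes the causal graph

    z1 -> x1        z1, z2 -> Z -> t -> y <- Z
    z2 -> x2

where z1 is a vector of Bernoulli latent confounders with discrete noisy
proxies x1 (aberration indicators, categorical clinical fields), z2 a
Gaussian latent vector with continuous proxies x2 (expression, continuous
clinical), and Z a joint confounder layer driving both the intervention t
(a binary genomic aberration) and the outcome y (Gleason Score).  The joint
density factorizes as

    p(Z, z1, z2, x1, x2, t, y)
      = p(z1) p(z2) p(x1|z1) p(x2|z2) p(Z|z1,z2) p(t|Z) p(y|t,Z).

Two variational autoencoders (one per latent block) plus a joint layer are
trained jointly by stochastic gradient ascent on the evidence lower bound

    E_q[log p(x1|z1) + log p(x2|z2) + log p(t|Z) + log p(y|t,Z)]
      - KL(q(z1|x1,t,y) || Bern(0.5))
      - KL(q(z2|x2,t,y) || N(0,I))
      - E_q[ KL(q(Z|z1,z2,t,y) || p(Z|z1,z2)) ],

with auxiliary predictors q(t|x) and q(y|t,x) trained alongside so that
inference remains possible when t or y is withheld.  Discrete latents use
relaxed-Bernoulli (concrete) samples during training and hard samples at
evaluation.  Counterfactual outcomes are posterior means of the outcome
head p(y | t', Z) evaluated at both intervention arms.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from . import nn
from .data import CohortTable, FeatureSchema
from .metrics import CounterfactualEstimates

__all__ = [
    "DLVMConfig",
    "TrainedDLVM",
    "fit_dlvm",
    "elbo",
    "infer_counterfactual",
    "reconstruct_factual",
]


@dataclass
class DLVMConfig:
    """Hyperparameters of the DLVM.

    Defaults are the reference configuration for real cohorts (latent
    dimensions 50/160/160, three sigmoid hidden layers of 300/300/100 units,
    Adam at learning rate 1e-5 with decay 1e-5, batch size 10, up to 300
    epochs).  :meth:`desk_scale` gives a small configuration sized for the
    synthetic cohorts used in tests and the worked examples.
    """

    dim_Z: int = 50
    dim_z1: int = 160
    dim_z2: int = 160
    hidden_sizes: tuple[int, ...] = (300, 300, 100)
    hidden_activation: str = "sigmoid"
    output_activation: str = "softmax"
    epochs: int = 300
    batch_size: int = 10
    learning_rate: float = 1e-5
    decay_rate: float = 1e-5
    optimizer: str = "adam"
    n_posterior_samples: int = 100
    outcome_model: str = "gaussian"
    seed: int = 0
    temperature: float = 0.5       # relaxed-Bernoulli temperature for z1
    aux_weight: float = 1.0        # weight of the auxiliary t/y predictors
    condition: str = "factual"     # posterior conditioning at inference

    def __post_init__(self):
        # coerce YAML-borne strings ("3e-3" is a string under YAML 1.1)
        for name in ("dim_Z", "dim_z1", "dim_z2", "epochs", "batch_size",
                     "n_posterior_samples", "seed"):
            setattr(self, name, int(getattr(self, name)))
        for name in ("learning_rate", "decay_rate", "temperature", "aux_weight"):
            setattr(self, name, float(getattr(self, name)))
        for name in ("dim_Z", "dim_z1", "dim_z2", "epochs", "batch_size",
                     "n_posterior_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.outcome_model not in ("gaussian", "ordinal-categorical"):
            raise ValueError("outcome_model must be 'gaussian' or 'ordinal-categorical'")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.condition not in ("factual", "proxies"):
            raise ValueError("condition must be 'factual' or 'proxies'")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "DLVMConfig":
        """Small-network configuration for synthetic desk-scale cohorts."""
        base = dict(
            dim_Z=16,
            dim_z1=16,
            dim_z2=16,
            hidden_sizes=(64, 32),
            hidden_activation="tanh",
            epochs=60,
            batch_size=100,
            learning_rate=3e-3,
            decay_rate=1e-5,
            n_posterior_samples=100,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


class _Preprocessor:
    """Deterministic feature encoding fitted on the training split.

    Discrete columns that are already 0/1 pass through; other categoricals
    are one-hot expanded with lexicographic level order.  Continuous columns
    are mean-imputed (training mean) and standardized; the outcome is
    standardized for the Gaussian head.
    """

    def fit(self, table: CohortTable) -> "_Preprocessor":
        s = table.schema
        frame = table.frame
        self.discrete_spec: list[tuple[str, tuple | None]] = []
        for col in s.discrete_columns:
            values = frame[col]
            numeric = set(pd_unique_no_nan(values))
            if numeric <= {0, 1, 0.0, 1.0}:
                self.discrete_spec.append((col, None))
            else:
                levels = tuple(sorted(str(v) for v in numeric))
                self.discrete_spec.append((col, levels))
        self.continuous_columns = s.continuous_columns
        cont = frame[list(s.continuous_columns)].to_numpy(dtype=float) if s.continuous_columns else np.zeros((table.n, 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.cont_mean = np.nan_to_num(np.nanmean(cont, axis=0)) if cont.size else np.zeros(0)
            sd = np.nanstd(cont, axis=0) if cont.size else np.zeros(0)
        self.cont_sd = np.where(sd > 0, sd, 1.0)
        self.n_imputed = int(np.isnan(cont).sum())
        y = table.outcome.astype(float)
        self.y_mean = float(y.mean())
        self.y_sd = float(y.std()) or 1.0
        self.y_classes = np.arange(int(y.min()), int(y.max()) + 1)
        return self

    def transform(self, table: CohortTable):
        frame = table.frame
        blocks = []
        for col, levels in self.discrete_spec:
            if levels is None:
                blocks.append(frame[col].to_numpy(dtype=float)[:, None])
            else:
                vals = frame[col].astype(str).to_numpy()
                blocks.append(np.stack([(vals == lv).astype(float) for lv in levels], axis=1))
        x1 = np.concatenate(blocks, axis=1) if blocks else np.zeros((table.n, 0))
        if self.continuous_columns:
            cont = frame[list(self.continuous_columns)].to_numpy(dtype=float)
            cont = np.where(np.isnan(cont), self.cont_mean, cont)
            x2 = (cont - self.cont_mean) / self.cont_sd
        else:
            x2 = np.zeros((table.n, 0))
        t = table.treatment.astype(float)
        y = table.outcome.astype(float)
        y_std = (y - self.y_mean) / self.y_sd
        return x1, x2, t, y, y_std

    def state(self) -> dict:
        return {
            "discrete_spec": [[c, list(lv) if lv else None] for c, lv in self.discrete_spec],
            "continuous_columns": list(self.continuous_columns),
            "cont_mean": self.cont_mean.tolist(),
            "cont_sd": self.cont_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "y_classes": self.y_classes.tolist(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "_Preprocessor":
        pp = cls()
        pp.discrete_spec = [(c, tuple(lv) if lv else None) for c, lv in state["discrete_spec"]]
        pp.continuous_columns = tuple(state["continuous_columns"])
        pp.cont_mean = np.array(state["cont_mean"])
        pp.cont_sd = np.array(state["cont_sd"])
        pp.y_mean = state["y_mean"]
        pp.y_sd = state["y_sd"]
        pp.y_classes = np.array(state["y_classes"])
        pp.n_imputed = 0
        return pp


def pd_unique_no_nan(series):
    vals = series.dropna().unique()
    return list(vals)


@dataclass
class TrainedDLVM:
    """A fitted DLVM: networks, preprocessing state and training log."""

    config: DLVMConfig
    schema_fingerprint: str
    nets: dict = field(repr=False, default_factory=dict)
    y_logvar: "nn.Tensor" = field(repr=False, default=None)
    preprocessor: _Preprocessor = field(repr=False, default=None)
    training_log: list = field(default_factory=list)  # (epoch, train, valid)

    # -- construction ----------------------------------------------------
    @classmethod
    def _build(cls, config: DLVMConfig, d1: int, d2: int, n_y_classes: int,
               fingerprint: str, rng: np.random.Generator) -> "TrainedDLVM":
        H, act = config.hidden_sizes, config.hidden_activation
        mk = lambda din, dout: nn.MLP(din, H, dout, rng, activation=act)
        y_out = 1 if config.outcome_model == "gaussian" else n_y_classes
        nets = {
            "enc_z1": mk(d1 + 2, config.dim_z1),
            "enc_z2": mk(d2 + 2, 2 * config.dim_z2),
            "enc_Z": mk(config.dim_z1 + config.dim_z2 + 2, 2 * config.dim_Z),
            "prior_Z": mk(config.dim_z1 + config.dim_z2, 2 * config.dim_Z),
            "dec_x1": mk(config.dim_z1, d1),
            "dec_x2": mk(config.dim_z2, 2 * d2) if d2 else None,
            "dec_t": mk(config.dim_Z, 1),
            "dec_y": mk(config.dim_Z + 1, y_out),
            "aux_t": mk(d1 + d2, 1),
            "aux_y": mk(d1 + d2 + 1, 1),
        }
        return cls(
            config=config,
            schema_fingerprint=fingerprint,
            nets=nets,
            y_logvar=nn.Tensor(np.zeros(1), requires_grad=True),
        )

    def parameters(self) -> list:
        params = [p for net in self.nets.values() if net is not None
                  for p in net.parameters()]
        params.append(self.y_logvar)
        return params

    def parameter_checksum(self) -> float:
        """Order-stable sum over all parameters; equal for identical fits."""
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    # -- pieces of the variational objective -----------------------------
    def _gauss_head(self, net_out, k):
        mu = nn.slice_cols(net_out, 0, k)
        logvar = nn.bounded_logvar(nn.slice_cols(net_out, k, 2 * k))
        return mu, logvar

    def _outcome_loglik(self, Z, t_col, y_raw, y_std):
        """log p(y | t, Z) and the head's predicted outcome (GS scale)."""
        out = self.nets["dec_y"](nn.concat([Z, t_col]))
        pp = self.preprocessor
        if self.config.outcome_model == "gaussian":
            lv = nn.bounded_logvar(self.y_logvar)
            ll = nn.gaussian_loglik(y_std[:, None], out, lv + nn.Tensor(np.zeros_like(out.data)))
            pred = out.data[:, 0] * pp.y_sd + pp.y_mean
            return ll, pred
        # ordinal-categorical: softmax over the observed GS levels
        logp = out - nn.logsumexp(out, axis=1, keepdims=True)
        onehot = (y_raw[:, None] == pp.y_classes[None, :]).astype(float)
        ll = (nn.Tensor(onehot) * logp).sum(axis=1)
        probs = np.exp(logp.data)
        pred = probs @ pp.y_classes
        return ll, pred

    def _elbo_graph(self, x1, x2, t, y_raw, y_std, rng, hard: bool):
        """One-sample ELBO per row plus auxiliary losses (Tensor outputs)."""
        cfg = self.config
        n = x1.shape[0]
        t_col = nn.Tensor(t[:, None])
        y_col = nn.Tensor(y_std[:, None])
        x1_t, x2_t = nn.Tensor(x1), nn.Tensor(x2)

        l1 = self.nets["enc_z1"](nn.concat([x1_t, t_col, y_col]))
        if hard:
            u = rng.random((n, cfg.dim_z1))
            s1 = nn.Tensor((u < expit(l1.data)).astype(float))
        else:
            u = rng.random((n, cfg.dim_z1))
            logistic = np.log(u) - np.log1p(-u)
            s1 = nn.sigmoid((l1 + nn.Tensor(logistic)) / cfg.temperature)

        mu2, lv2 = self._gauss_head(self.nets["enc_z2"](nn.concat([x2_t, t_col, y_col])), cfg.dim_z2)
        z2 = mu2 + nn.exp(0.5 * lv2) * nn.Tensor(rng.standard_normal((n, cfg.dim_z2)))

        muZ, lvZ = self._gauss_head(self.nets["enc_Z"](nn.concat([s1, z2, t_col, y_col])), cfg.dim_Z)
        Z = muZ + nn.exp(0.5 * lvZ) * nn.Tensor(rng.standard_normal((n, cfg.dim_Z)))
        mup, lvp = self._gauss_head(self.nets["prior_Z"](nn.concat([s1, z2])), cfg.dim_Z)

        ll = nn.bernoulli_loglik(x1, self.nets["dec_x1"](s1))
        if x2.shape[1]:
            mux, lvx = self._gauss_head(self.nets["dec_x2"](z2), x2.shape[1])
            ll = ll + nn.gaussian_loglik(x2, mux, lvx)
        ll = ll + nn.bernoulli_loglik(t[:, None], self.nets["dec_t"](Z))
        ll_y, _ = self._outcome_loglik(Z, t_col, y_raw, y_std)
        ll = ll + ll_y

        kl = (
            nn.kl_bernoulli_uniform(l1)
            + nn.kl_gaussian_standard(mu2, lv2)
            + nn.kl_gaussian_gaussian(muZ, lvZ, mup, lvp)
        )
        elbo_rows = ll - kl

        x_all = nn.concat([x1_t, x2_t])
        aux_t_ll = nn.bernoulli_loglik(t[:, None], self.nets["aux_t"](x_all))
        aux_y_pred = self.nets["aux_y"](nn.concat([x_all, t_col]))
        aux_loss = -aux_t_ll.mean() + ((aux_y_pred - y_col) ** 2).sum(axis=1).mean()
        return elbo_rows, aux_loss

    # -- posterior sampling (no gradients) -------------------------------
    def _posterior_means(self, cohort: CohortTable, n_samples: int,
                         rng: np.random.Generator, condition: str):
        """Posterior-mean outcome under both arms, via common random numbers.

        One shared noise stream (per sample index, not per patient) is used
        for every patient, so row permutations permute the output exactly.
        """
        cfg = self.config
        pp = self.preprocessor
        x1, x2, t, y_raw, y_std = pp.transform(cohort)
        n = x1.shape[0]

        if condition == "proxies":
            x_all = np.concatenate([x1, x2], axis=1)
            p_t = expit(self.nets["aux_t"](nn.Tensor(x_all)).data[:, 0])
            t_cond = (p_t > 0.5).astype(float)
            y_cond = self.nets["aux_y"](
                nn.Tensor(np.concatenate([x_all, t_cond[:, None]], axis=1))
            ).data[:, 0]
        else:
            t_cond, y_cond = t, y_std

        tc = nn.Tensor(t_cond[:, None])
        yc = nn.Tensor(y_cond[:, None])
        l1 = self.nets["enc_z1"](nn.concat([nn.Tensor(x1), tc, yc])).data
        q1 = expit(l1)
        mu2, lv2 = self._gauss_head(self.nets["enc_z2"](nn.concat([nn.Tensor(x2), tc, yc])), cfg.dim_z2)
        sd2 = np.exp(0.5 * lv2.data)

        u_all = rng.random((n_samples, cfg.dim_z1))
        e2_all = rng.standard_normal((n_samples, cfg.dim_z2))
        eZ_all = rng.standard_normal((n_samples, cfg.dim_Z))

        acc0 = np.zeros(n)
        acc1 = np.zeros(n)
        for s in range(n_samples):
            s1 = (u_all[s][None, :] < q1).astype(float)
            z2 = mu2.data + sd2 * e2_all[s][None, :]
            muZ, lvZ = self._gauss_head(
                self.nets["enc_Z"](nn.concat([nn.Tensor(s1), nn.Tensor(z2), tc, yc])),
                cfg.dim_Z,
            )
            Z = nn.Tensor(muZ.data + np.exp(0.5 * lvZ.data) * eZ_all[s][None, :])
            for arm, acc in ((0.0, acc0), (1.0, acc1)):
                arm_col = nn.Tensor(np.full((n, 1), arm))
                _, pred = self._outcome_loglik(Z, arm_col, y_raw, y_std)
                acc += pred
        return acc0 / n_samples, acc1 / n_samples, t, y_raw


def fit_dlvm(train: CohortTable, valid: CohortTable | None, config: DLVMConfig) -> TrainedDLVM:
    """Train the DLVM by stochastic gradient ascent on the ELBO.

    Model selection keeps the parameters with the best validation ELBO seen
    during training (``valid=None`` keeps the final epoch).  Fully
    deterministic for a fixed ``config.seed``.
    """
    if train.n == 0:
        raise ValueError("training cohort is empty")
    if valid is not None and train.schema.fingerprint() != valid.schema.fingerprint():
        raise ValueError("train and validation schemas differ")
    t = train.treatment
    if t.min() == t.max():
        warnings.warn(
            "all training patients share one intervention arm; the "
            "counterfactual arm is unidentifiable from data alone",
            UserWarning,
        )

    children = np.random.SeedSequence(config.seed).spawn(4)
    init_rng = np.random.default_rng(children[0])
    batch_rng = np.random.default_rng(children[1])
    sample_rng = np.random.default_rng(children[2])
    eval_seed = int(children[3].generate_state(1)[0] % (2**31))

    pp = _Preprocessor().fit(train)
    x1, x2, t_arr, y_raw, y_std = pp.transform(train)
    model = TrainedDLVM._build(
        config, x1.shape[1], x2.shape[1], len(pp.y_classes),
        train.schema.fingerprint(), init_rng,
    )
    model.preprocessor = pp

    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.decay_rate)
    n = train.n
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        order = batch_rng.permutation(n)
        epoch_elbo = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            elbo_rows, aux_loss = model._elbo_graph(
                x1[idx], x2[idx], t_arr[idx], y_raw[idx], y_std[idx],
                sample_rng, hard=False,
            )
            loss = -elbo_rows.mean() + config.aux_weight * aux_loss
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_elbo += float(elbo_rows.data.sum())
        train_elbo = epoch_elbo / n

        if valid is not None and valid.n:
            val_elbo = elbo(model, valid, n_samples=2, seed=eval_seed)
            if val_elbo > best[0]:
                best = (val_elbo, [p.data.copy() for p in model.parameters()])
        else:
            val_elbo = float("nan")
        model.training_log.append((epoch, train_elbo, val_elbo))

    if best[1] is not None:
        for p, data in zip(model.parameters(), best[1]):
            p.data = data
    return model


def elbo(model: TrainedDLVM, batch: CohortTable, n_samples: int | None = None,
         seed: int | None = None) -> float:
    """Monte-Carlo estimate of the per-patient evidence lower bound.

    Uses hard Bernoulli samples for z1 and ``n_samples`` posterior draws
    (default ``config.n_posterior_samples``); returns the mean over patients.
    """
    if batch.n == 0:
        raise ValueError("batch is empty")
    if model.preprocessor is None:
        raise ValueError("model is not trained")
    if batch.schema.fingerprint() != model.schema_fingerprint:
        raise ValueError("batch schema does not match the model's schema")
    S = n_samples or model.config.n_posterior_samples
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    x1, x2, t, y_raw, y_std = model.preprocessor.transform(batch)
    total = 0.0
    for _ in range(S):
        rows, _ = model._elbo_graph(x1, x2, t, y_raw, y_std, rng, hard=True)
        total += float(rows.data.mean())
    return total / S


def infer_counterfactual(model: TrainedDLVM, cohort: CohortTable,
                         n_samples: int | None = None, seed: int | None = None,
                         condition: str | None = None) -> CounterfactualEstimates:
    """Posterior-mean potential outcomes and ICE for every patient.

    Draws ``n_samples`` joint posterior samples of (z1, z2, Z) conditioned on
    the proxies plus — under the default ``condition="factual"`` — the
    factual intervention and outcome, and evaluates the outcome head at both
    arms.  ``condition="proxies"`` instead seeds the encoder with the
    auxiliary predictors' (t, y), for cohorts where y must be withheld.
    """
    if model.preprocessor is None:
        raise ValueError("model is not trained")
    if cohort.schema.fingerprint() != model.schema_fingerprint:
        raise ValueError("cohort schema does not match the model's schema")
    S = n_samples or model.config.n_posterior_samples
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    cond = condition or model.config.condition
    y0, y1, t, y_raw = model._posterior_means(cohort, S, rng, cond)
    return CounterfactualEstimates(y_hat_0=y0, y_hat_1=y1, t_factual=t.astype(int),
                                   y_factual=y_raw)


def reconstruct_factual(model: TrainedDLVM, cohort: CohortTable,
                        n_samples: int | None = None, seed: int | None = None) -> np.ndarray:
    """Estimated outcome at each patient's factual arm (same machinery as
    :func:`infer_counterfactual`; returns the factual-arm column)."""
    est = infer_counterfactual(model, cohort, n_samples=n_samples, seed=seed)
    return est.y_hat_factual


# -- checkpointing --------------------------------------------------------

def save_dlvm(model: TrainedDLVM, path) -> None:
    """Serialize a fitted model (single .npz archive with embedded config)."""
    meta = {
        "config": asdict(model.config),
        "schema_fingerprint": model.schema_fingerprint,
        "preprocessor": model.preprocessor.state(),
        "net_shapes": {k: v is not None for k, v in model.nets.items()},
        "training_log": model.training_log,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_dlvm(path, schema: FeatureSchema) -> TrainedDLVM:
    """Load a checkpoint; refuses to load against a mismatched schema."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta["schema_fingerprint"] != schema.fingerprint():
            raise ValueError("checkpoint schema fingerprint does not match")
        cfg = DLVMConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in meta["config"].items()})
        pp = _Preprocessor.from_state(meta["preprocessor"])
        d1 = sum(1 if lv is None else len(lv) for _, lv in pp.discrete_spec)
        d2 = len(pp.continuous_columns)
        rng = np.random.default_rng(0)
        model = TrainedDLVM._build(cfg, d1, d2, len(pp.y_classes),
                                   meta["schema_fingerprint"], rng)
        model.preprocessor = pp
        model.training_log = [tuple(row) for row in meta["training_log"]]
        for i, p in enumerate(model.parameters()):
            p.data = archive[f"param_{i}"]
    return model
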