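"""Closed-loop control of network contraction by reinforcement learning.

The agent observes the radial displacement U_r(r0, t) at a fixed radius
r0 and chooses, at each control interval, the radius and amplitude of a
sigmoidal azimuthally symmetric light profile.  The reward drives
U_r(r0, t) along the trajectory of an overdamped spring relaxing to a
target displacement U_goal with rate k_spring, so one task family sets
the set-point and another shapes the rate of approach.

Training uses the deep deterministic policy gradient (DDPG) actor-critic
algorithm.  The implementation here is a compact, self-contained numpy
one: two small multilayer perceptrons with manual backpropagation and
Adam, target networks with soft updates, a replay buffer, and temporally
correlated (Ornstein-Uhlenbeck) exploration noise with linear decay —
the correlated noise matters, because discovering the "back off the
light" half of the policy requires sustained low-amplitude excursions.
Observation latency is randomized during training so the learned policy
tolerates delayed measurements, and the returned actor is the checkpoint
with the best greedy settling score over independent restarts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .chemistry import species_diffusivities
from .core import ModelParams, RadialGrid, validate_params
from .illumination import LightProtocol
from .simulate import _check_state, _mech_velocity, _rhs_radial, initial_chem, stable_dt

__all__ = [
    "ControlTask",
    "PolicySpec",
    "Policy",
    "TcbEnv",
    "spring_reference",
    "train_ddpg",
    "evaluate_policy",
    "save_policy",
    "load_policy",
]


@dataclass
class ControlTask:
    """Set-point / rate-shaping displacement-control task definition."""

    U_goal: float               # target displacement at r0 (um), negative = inward
    k_spring: float = 0.2       # reference spring rate (1/s)
    r0: float = 50.0            # observation radius (um)
    dt_control: float = 1.0     # control interval (s)
    horizon: int = 30           # episode length in control steps
    rho_min: float = 10.0       # light radius bounds (um)
    rho_max: float = 70.0
    A_max: float = 0.05         # light amplitude bound (arb. units);
                                # the bound already gives near-complete
                                # uncaging within one control interval
    w_s: float = 5.0            # sigmoid light profile width (um)
    observe_ref: bool = True    # augment observation with (U_ref, t/T)

    def validate(self, grid: RadialGrid) -> "ControlTask":
        if not (0.0 < self.r0 < grid.R_max):
            raise ValueError(f"r0 must lie strictly inside the grid, got {self.r0}")
        if self.k_spring <= 0:
            raise ValueError("k_spring must be positive")
        if not (0.0 < self.rho_min < self.rho_max < grid.R_max):
            raise ValueError("need 0 < rho_min < rho_max < R_max")
        if self.A_max <= 0 or self.dt_control <= 0 or self.horizon < 1:
            raise ValueError("A_max, dt_control and horizon must be positive")
        return self


def spring_reference(U0: float, task: ControlTask, times) -> np.ndarray:
    """Overdamped-spring reference U_ref(t) = U_goal + (U0 - U_goal) e^{-k t}."""
    t = np.asarray(times, dtype=float)
    return task.U_goal + (U0 - task.U_goal) * np.exp(-task.k_spring * t)


# --------------------------------------------------------------------------
class TcbEnv:
    """The coupled chemomechanical simulator as a control environment.

    ``reset()`` restores the uniform initial state (optionally jittering
    the chemical pool concentrations by a few percent, emulating
    sample-to-sample pipetting variability, from the env's seeded rng);
    ``step((rho, A))`` advances the full simulation by one control
    interval under the sigmoidal light profile and returns
    ``(observation, reward, done, info)`` with
    reward = -(U_r(r0) - U_ref)^2.  Out-of-bounds actions are clipped.
    """

    def __init__(self, params: ModelParams, grid: RadialGrid, task: ControlTask,
                 safety: float = 0.4, seed: Optional[int] = None,
                 pool_jitter: float = 0.0):
        self.params = validate_params(params)
        self.grid = grid
        self.task = task.validate(grid)
        self.pool_jitter = float(pool_jitter)
        self.rng = np.random.default_rng(seed)
        # fix dt so that dt_control is an integer multiple of it
        dt0 = stable_dt(params, grid, safety, amplitude=task.A_max)
        self.n_sub = int(np.ceil(task.dt_control / dt0))
        self.dt = task.dt_control / self.n_sub
        self._D = species_diffusivities(params)
        self.obs_dim = 3 if task.observe_ref else 1
        self.act_dim = 2
        self._u_scale = max(abs(task.U_goal), 1e-6)
        self.reset()

    # -- helpers ------------------------------------------------------------
    def _observe(self, U_meas: float) -> np.ndarray:
        t = self.k * self.task.dt_control
        if not self.task.observe_ref:
            return np.array([U_meas / self._u_scale])
        ref = spring_reference(self.U0_obs, self.task, t)
        T = self.task.horizon * self.task.dt_control
        return np.array([U_meas / self._u_scale, ref / self._u_scale, t / T])

    def u_at_r0(self) -> float:
        return float(np.interp(self.task.r0, self.grid.r, self.U))

    def reset(self) -> np.ndarray:
        p = self.params
        if self.pool_jitter > 0:
            fac = 1.0 + self.pool_jitter * self.rng.uniform(-1, 1, size=2)
            import dataclasses

            p = dataclasses.replace(
                p,
                C_T_tot=p.C_T_tot * fac[0],
                C_D_tot=p.C_D_tot * fac[1],
                C_Ca_tot=p.C_Ca_tot * fac[1],  # premixed 2:1, jitter together
            )
        self._p = p
        self.y = initial_chem(p, self.grid.n_nodes)
        self.U = np.zeros(self.grid.n_nodes)
        self.k = 0
        self.U0_obs = 0.0
        return self._observe(self.u_at_r0())

    def step(self, action):
        task = self.task
        rho = float(np.clip(action[0], task.rho_min, task.rho_max))
        A = float(np.clip(action[1], 0.0, task.A_max))
        proto = LightProtocol(kind="sigmoid_control", A=A, rho=rho, w_s=task.w_s)
        prof = proto.radial_profile(self.grid.r)
        p, grid, dt, D = self._p, self.grid, self.dt, self._D
        y, U = self.y, self.U
        from ._kernel import HAVE_NUMBA, integrate_block, pack_params
        from .chemistry import SPECIES

        if HAVE_NUMBA:
            ones = np.ones(self.n_sub)
            status, _, s, node = integrate_block(
                y, U, pack_params(p), grid.r, grid.dr, D, prof, ones, ones, dt)
            if status != 0:
                from .simulate import IntegrationError

                raise IntegrationError(
                    f"integration failed in field {SPECIES[s]} at node "
                    f"{node} during control step {self.k + 1}")
        else:
            for _ in range(self.n_sub):
                k1y, k1U = _rhs_radial(y, U, prof, p, grid, D)
                y_p = y + dt * k1y
                U_p = U + dt * k1U
                k2y, k2U = _rhs_radial(y_p, U_p, prof, p, grid, D)
                y += 0.5 * dt * (k1y + k2y)
                U += 0.5 * dt * (k1U + k2U)
                U[0] = U[-1] = 0.0
        self.k += 1
        t = self.k * task.dt_control
        _check_state(y, t)
        u = self.u_at_r0()
        ref = float(spring_reference(self.U0_obs, task, t))
        reward = -(u - ref) ** 2
        done = self.k >= task.horizon
        info = {"t": t, "U": u, "U_ref": ref, "rho": rho, "A": A}
        return self._observe(u), reward, done, info


# -- tiny MLP with manual backprop ------------------------------------------
class _MLP:
    """Fully connected net, tanh hidden layers, linear output."""

    def __init__(self, sizes, rng):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, x):
        self._acts = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = np.tanh(z) if i < len(self.W) - 1 else z
            self._acts.append(h)
        return h

    def backward(self, grad_out):
        """Grads of sum(grad_out * output) w.r.t. params and input."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        for i in reversed(range(len(self.W))):
            h_in = self._acts[i]
            if i < len(self.W) - 1:
                g = g * (1.0 - self._acts[i + 1] ** 2)
            gW[i] = h_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW, gb, g

    @property
    def params(self):
        return self.W + self.b

    def copy_from(self, other, tau=1.0):
        for dst, src in zip(self.params, other.params):
            dst *= 1.0 - tau
            dst += tau * src


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class PolicySpec:
    """DDPG hyperparameters (defaults sized for the reduced-resolution env)."""

    actor_hidden: tuple = (64, 64)
    critic_hidden: tuple = (128, 128)
    episodes: int = 400
    discount: float = 0.98
    tau: float = 0.02           # target-network soft-update rate
    replay_capacity: int = 50_000
    batch_size: int = 128
    lr_actor: float = 3e-4
    lr_critic: float = 1e-3
    noise_scale: float = 0.3    # exploration std (normalized actions)
    noise_final: float = 0.02   # linear decay endpoint
    noise_kind: str = "ou"      # 'ou' (temporally correlated) or 'gaussian'
    ou_theta: float = 0.15      # OU mean-reversion rate (per control step)
    eval_every: int = 10        # greedy checkpoint evaluation cadence
                                # (0 disables best-checkpoint selection)
    train_latency_max: int = 3  # per-episode observation latency randomized
                                # over {0..max} control steps (robustness)
    restarts: int = 2           # independent trainings; best settling score wins
    warmup: int = 300           # transitions before updates begin
    seed: int = 0

    def validate(self) -> "PolicySpec":
        if not (0.0 < self.discount <= 1.0):
            raise ValueError("discount must be in (0, 1]")
        if min(self.actor_hidden + self.critic_hidden) < 1:
            raise ValueError("layer sizes must be positive")
        if self.episodes < 1 or self.batch_size < 1 or self.replay_capacity < 1:
            raise ValueError("episodes, batch_size, replay_capacity must be >= 1")
        if self.noise_kind not in ("ou", "gaussian"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        return self


class Policy:
    """Greedy deterministic actor mapping observation -> (rho, A)."""

    def __init__(self, actor: _MLP, task: ControlTask, spec: PolicySpec,
                 training_curve=None):
        self.actor = actor
        self.task = task
        self.spec = spec
        self.training_curve = (np.asarray(training_curve)
                               if training_curve is not None else None)

    def _scale(self, a_norm: np.ndarray) -> np.ndarray:
        t = self.task
        rho = t.rho_min + 0.5 * (a_norm[..., 0] + 1.0) * (t.rho_max - t.rho_min)
        # quadratic amplitude map: fine resolution at the gentle end, where
        # the photolysis response would otherwise saturate within one step
        A = t.A_max * (0.5 * (a_norm[..., 1] + 1.0)) ** 2
        return np.stack([rho, A], axis=-1)

    def act_norm(self, obs: np.ndarray) -> np.ndarray:
        return np.tanh(self.actor.forward(np.atleast_2d(obs)))

    def __call__(self, obs: np.ndarray) -> np.ndarray:
        return self._scale(self.act_norm(obs))[0]


def train_ddpg(env: TcbEnv, spec: PolicySpec, task: ControlTask) -> Policy:
    """Train a DDPG actor-critic on the control environment.

    Runs ``spec.restarts`` independent trainings (sub-seeded from
    ``spec.seed``) and returns the greedy policy with the best settling
    score; the per-episode return curve of that run is attached.
    Deterministic given the spec seed and the env seed.  Raises if the
    returns diverge to NaN.
    """
    spec = spec.validate()
    results = []
    for r in range(spec.restarts):
        results.append(_train_once(env, spec, task,
                                   seed=spec.seed * 1009 + r))
    best = max(results, key=lambda item: item[1])
    return best[0]


def _train_once(env: TcbEnv, spec: PolicySpec, task: ControlTask,
                seed: int):
    rng = np.random.default_rng(seed)
    obs_dim, act_dim = env.obs_dim, env.act_dim
    actor = _MLP([obs_dim, *spec.actor_hidden, act_dim], rng)
    critic = _MLP([obs_dim + act_dim, *spec.critic_hidden, 1], rng)
    actor_t = _MLP([obs_dim, *spec.actor_hidden, act_dim], rng)
    critic_t = _MLP([obs_dim + act_dim, *spec.critic_hidden, 1], rng)
    actor_t.copy_from(actor)
    critic_t.copy_from(critic)
    opt_a = _Adam(actor.params, spec.lr_actor)
    opt_c = _Adam(critic.params, spec.lr_critic)
    policy = Policy(actor, task, spec)

    cap = spec.replay_capacity
    buf = {
        "s": np.zeros((cap, obs_dim)), "a": np.zeros((cap, act_dim)),
        "r": np.zeros(cap), "s2": np.zeros((cap, obs_dim)),
        "d": np.zeros(cap),
    }
    n_stored = 0

    def update():
        idx = rng.integers(0, min(n_stored, cap), size=spec.batch_size)
        s, a, r, s2, d = (buf["s"][idx], buf["a"][idx], buf["r"][idx],
                          buf["s2"][idx], buf["d"][idx])
        # critic target
        a2 = np.tanh(actor_t.forward(s2))
        q2 = critic_t.forward(np.concatenate([s2, a2], axis=1))[:, 0]
        y = r + spec.discount * (1.0 - d) * q2
        q = critic.forward(np.concatenate([s, a], axis=1))[:, 0]
        gq = ((q - y) / spec.batch_size)[:, None]
        gW, gb, _ = critic.backward(gq)
        opt_c.step(gW + gb)
        # actor: ascend Q(s, pi(s))
        z = actor.forward(s)
        a_pi = np.tanh(z)
        q_in = np.concatenate([s, a_pi], axis=1)
        critic.forward(q_in)
        _, _, g_in = critic.backward(np.full((spec.batch_size, 1),
                                             -1.0 / spec.batch_size))
        g_a = g_in[:, obs_dim:] * (1.0 - a_pi ** 2)
        gW, gb, _ = actor.backward(g_a)
        opt_a.step(gW + gb)
        actor_t.copy_from(actor, spec.tau)
        critic_t.copy_from(critic, spec.tau)

    def greedy_return() -> float:
        """Greedy settling score: late-episode return plus an extra penalty
        on the terminal hold error, averaged over zero and maximal
        observation latency (selects precise, latency-robust holds)."""
        late_from = task.horizon // 2
        totals = []
        for lat in (0, spec.train_latency_max):
            env.reset()
            u_hist = [env.u_at_r0()]
            done = False
            total = 0.0
            while not done:
                obs = env._observe(u_hist[max(len(u_hist) - 1 - lat, 0)])
                _, r, done, info = env.step(policy(obs))
                u_hist.append(info["U"])
                if env.k > late_from:
                    total += r
            # weight the terminal hold error heavily: the settling sum alone
            # can prefer a smooth-but-offset hold over a centered one
            total -= 30.0 * (u_hist[-1] - task.U_goal) ** 2
            totals.append(total)
        return float(np.mean(totals))

    curve = []
    best_score = -np.inf
    best_weights = None
    for ep in range(spec.episodes):
        frac = ep / max(spec.episodes - 1, 1)
        sigma = spec.noise_scale + frac * (spec.noise_final - spec.noise_scale)
        env.reset()
        lat = (int(rng.integers(0, spec.train_latency_max + 1))
               if spec.train_latency_max else 0)
        u_hist = [env.u_at_r0()]
        obs = env._observe(u_hist[0])
        ep_ret = 0.0
        done = False
        ou = np.zeros(act_dim)
        while not done:
            a_norm = policy.act_norm(obs)[0]
            if spec.noise_kind == "ou":
                ou += -spec.ou_theta * ou + sigma * rng.standard_normal(act_dim)
                noise = ou
            else:
                noise = sigma * rng.standard_normal(act_dim)
            a_norm = np.clip(a_norm + noise, -1.0, 1.0)
            action = policy._scale(a_norm)
            _, r, done, info = env.step(action)
            u_hist.append(info["U"])
            obs2 = env._observe(u_hist[max(len(u_hist) - 1 - lat, 0)])
            j = n_stored % cap
            buf["s"][j], buf["a"][j], buf["r"][j] = obs, a_norm, r
            buf["s2"][j], buf["d"][j] = obs2, float(done)
            n_stored += 1
            if n_stored >= spec.warmup:
                update()
            obs = obs2
            ep_ret += r
        if not np.isfinite(ep_ret):
            raise RuntimeError(f"training diverged (episode {ep}: return {ep_ret})")
        curve.append(ep_ret)
        # periodic greedy evaluation; keep the best actor seen (guards
        # against late-training policy collapse)
        if spec.eval_every and (ep + 1) % spec.eval_every == 0 \
                and n_stored >= spec.warmup:
            score = greedy_return()
            if score > best_score:
                best_score = score
                best_weights = [w.copy() for w in actor.params]
    if best_weights is not None:
        for dst, src in zip(actor.params, best_weights):
            dst[...] = src
    if not np.isfinite(best_score):
        best_score = greedy_return()
    policy.training_curve = np.asarray(curve)
    return policy, best_score


def evaluate_policy(policy: Policy, env: TcbEnv, n_episodes: int,
                    latency: float = 0.0) -> dict:
    """Greedy rollouts, optionally with delayed observations.

    ``latency`` (s) must be an integer number of control steps; the policy
    then acts on the displacement measured ``latency`` seconds ago (the
    reference and clock channels stay current).  Returns mean final
    displacement, tracking RMSE, and the per-step actions of each episode.
    """
    task = env.task
    n_delay = latency / task.dt_control
    if latency < 0 or abs(n_delay - round(n_delay)) > 1e-9:
        raise ValueError(
            f"latency must be a non-negative integer multiple of "
            f"dt_control = {task.dt_control}, got {latency}"
        )
    n_delay = int(round(n_delay))
    finals, rmses, all_actions = [], [], []
    for _ in range(n_episodes):
        env.reset()
        u_hist = [env.u_at_r0()]
        errors, actions = [], []
        done = False
        while not done:
            u_stale = u_hist[max(len(u_hist) - 1 - n_delay, 0)]
            obs = env._observe(u_stale)
            action = policy(obs)
            _, _, done, info = env.step(action)
            u_hist.append(info["U"])
            errors.append(info["U"] - info["U_ref"])
            actions.append((info["rho"], info["A"]))
        finals.append(u_hist[-1])
        rmses.append(float(np.sqrt(np.mean(np.square(errors)))))
        all_actions.append(actions)
    return {
        "final_displacement": float(np.mean(finals)),
        "final_displacements": finals,
        "tracking_rmse": float(np.mean(rmses)),
        "actions": np.asarray(all_actions),
    }


# -- policy serialization ----------------------------------------------------
def save_policy(policy: Policy, path) -> None:
    """Serialize the actor weights with architecture and task metadata (npz)."""
    arrays = {}
    for i, W in enumerate(policy.actor.W):
        arrays[f"W{i}"] = W
    for i, b in enumerate(policy.actor.b):
        arrays[f"b{i}"] = b
    if policy.training_curve is not None:
        arrays["training_curve"] = policy.training_curve
    meta = {"task": asdict(policy.task), "spec": asdict(policy.spec)}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_policy(path) -> Policy:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        task = ControlTask(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in meta["task"].items()})
        spec = PolicySpec(**{k: (tuple(v) if isinstance(v, list) else v)
                             for k, v in meta["spec"].items()})
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        actor = _MLP([1, 1], np.random.default_rng(0))
        actor.W = [data[f"W{i}"] for i in range(n_layers)]
        actor.b = [data[f"b{i}"] for i in range(n_layers)]
        curve = data.get("training_curve")
        return Policy(actor, task, spec,
                      curve if curve is not None else None)
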