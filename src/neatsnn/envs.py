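"""Bundled episodic control environments and the adapter contract.

Every environment exposes the minimal episodic contract::

    obs = env.reset(seed)                      # observation vector
    obs, reward, terminated, truncated = env.step(action)

plus ``observation_dim``, ``n_actions``, ``step_limit``,
``observation_ranges`` (an (F, 2) array of characteristic bounds used by
the interval-coding input bank) and ``observation_scales`` (per-feature
magnitudes used by the sign-split encoder).

The three bundled tasks re-implement the standard published benchmark
dynamics:

* CartPole — balance a pole on a force-controlled cart; +1 reward per step,
  episode ends when the pole tips past 12 degrees or the cart leaves
  +-2.4, truncated at 500 steps (maximum return 500).
* MountainCar — drive an under-powered car out of a valley by building
  momentum; -1 per step, 200-step cap (minimum return -200).
* Acrobot — swing a two-link pendulum's tip above the bar; -1 per step,
  500-step cap, solved around -100.

Any external Gymnasium-style environment can be used through
:class:`GymnasiumAdapter`.
"""

from __future__ import annotations

import math
from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class EnvAdapter(Protocol):
    observation_dim: int
    n_actions: int
    step_limit: int

    def reset(self, seed: int | None = None) -> np.ndarray: ...

    def step(self, action: int
             ) -> tuple[np.ndarray, float, bool, bool]: ...


def _generator(seed: int | None) -> np.random.Generator:
    ss = np.random.SeedSequence(seed) if seed is not None \
        else np.random.SeedSequence()
    return np.random.Generator(np.random.PCG64(ss))


class CartPole:
    """Pole-balancing with the classic cart-pole physics (Euler, 0.02 s)."""

    observation_dim = 4
    n_actions = 2
    step_limit = 500
    # position, velocity, angle, angular velocity
    observation_ranges = np.array([[-2.4, 2.4], [-3.0, 3.0],
                                   [-0.2095, 0.2095], [-3.0, 3.0]])
    observation_scales = np.array([2.4, 3.0, 0.2095, 3.0])

    gravity = 9.8
    mass_cart = 1.0
    mass_pole = 0.1
    length = 0.5          # half the pole length
    force_mag = 10.0
    tau = 0.02            # s per control step
    theta_limit = 12.0 * math.pi / 180.0
    x_limit = 2.4

    def __init__(self):
        self._state = None
        self._steps = 0

    def reset(self, seed: int | None = None) -> np.ndarray:
        rng = _generator(seed)
        self._state = rng.uniform(-0.05, 0.05, size=4)
        self._steps = 0
        return self._state.copy()

    def step(self, action: int):
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        if action not in (0, 1):
            raise ValueError(f"invalid action {action}")
        x, x_dot, theta, theta_dot = self._state
        force = self.force_mag if action == 1 else -self.force_mag
        total_mass = self.mass_cart + self.mass_pole
        pm_length = self.mass_pole * self.length
        cos_t, sin_t = math.cos(theta), math.sin(theta)
        temp = (force + pm_length * theta_dot ** 2 * sin_t) / total_mass
        theta_acc = (self.gravity * sin_t - cos_t * temp) / (
            self.length * (4.0 / 3.0 - self.mass_pole * cos_t ** 2
                           / total_mass))
        x_acc = temp - pm_length * theta_acc * cos_t / total_mass
        x += self.tau * x_dot
        x_dot += self.tau * x_acc
        theta += self.tau * theta_dot
        theta_dot += self.tau * theta_acc
        self._state = np.array([x, x_dot, theta, theta_dot])
        self._steps += 1
        terminated = bool(abs(x) > self.x_limit
                          or abs(theta) > self.theta_limit)
        truncated = bool(self._steps >= self.step_limit and not terminated)
        return self._state.copy(), 1.0, terminated, truncated


class MountainCar:
    """Under-powered car in a valley; discrete actions push left / coast /
    push right."""

    observation_dim = 2
    n_actions = 3
    step_limit = 200
    observation_ranges = np.array([[-1.2, 0.6], [-0.07, 0.07]])
    observation_scales = np.array([1.2, 0.07])

    min_position = -1.2
    max_position = 0.6
    max_speed = 0.07
    goal_position = 0.5
    force = 0.001
    gravity = 0.0025

    def __init__(self):
        self._state = None
        self._steps = 0

    def reset(self, seed: int | None = None) -> np.ndarray:
        rng = _generator(seed)
        self._state = np.array([rng.uniform(-0.6, -0.4), 0.0])
        self._steps = 0
        return self._state.copy()

    def step(self, action: int):
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        if action not in (0, 1, 2):
            raise ValueError(f"invalid action {action}")
        position, velocity = self._state
        velocity += (action - 1) * self.force \
            + math.cos(3 * position) * (-self.gravity)
        velocity = float(np.clip(velocity, -self.max_speed, self.max_speed))
        position += velocity
        position = float(np.clip(position, self.min_position,
                                 self.max_position))
        if position <= self.min_position and velocity < 0:
            velocity = 0.0
        self._state = np.array([position, velocity])
        self._steps += 1
        terminated = bool(position >= self.goal_position)
        truncated = bool(self._steps >= self.step_limit and not terminated)
        return self._state.copy(), -1.0, terminated, truncated


class Acrobot:
    """Two-link underactuated pendulum (torque on the elbow joint), RK4
    integration of the standard dynamics; observation is
    (cos t1, sin t1, cos t2, sin t2, w1, w2)."""

    observation_dim = 6
    n_actions = 3
    step_limit = 500
    _w1_max = 4 * math.pi
    _w2_max = 9 * math.pi
    observation_ranges = np.array([[-1.0, 1.0], [-1.0, 1.0], [-1.0, 1.0],
                                   [-1.0, 1.0], [-_w1_max, _w1_max],
                                   [-_w2_max, _w2_max]])
    observation_scales = np.array([1.0, 1.0, 1.0, 1.0, _w1_max, _w2_max])

    dt = 0.2
    link_length_1 = 1.0
    link_mass_1 = 1.0
    link_mass_2 = 1.0
    link_com_1 = 0.5
    link_com_2 = 0.5
    link_moi = 1.0
    g = 9.8
    torques = (-1.0, 0.0, 1.0)

    def __init__(self):
        self._s = None  # (theta1, theta2, w1, w2)
        self._steps = 0

    def reset(self, seed: int | None = None) -> np.ndarray:
        rng = _generator(seed)
        self._s = rng.uniform(-0.1, 0.1, size=4)
        self._steps = 0
        return self._obs()

    def _obs(self) -> np.ndarray:
        t1, t2, w1, w2 = self._s
        return np.array([math.cos(t1), math.sin(t1), math.cos(t2),
                         math.sin(t2), w1, w2])

    def _dsdt(self, s: np.ndarray, torque: float) -> np.ndarray:
        m1, m2 = self.link_mass_1, self.link_mass_2
        l1 = self.link_length_1
        lc1, lc2 = self.link_com_1, self.link_com_2
        I1 = I2 = self.link_moi
        g = self.g
        t1, t2, w1, w2 = s
        d1 = (m1 * lc1 ** 2 + m2 *
              (l1 ** 2 + lc2 ** 2 + 2 * l1 * lc2 * math.cos(t2)) + I1 + I2)
        d2 = m2 * (lc2 ** 2 + l1 * lc2 * math.cos(t2)) + I2
        phi2 = m2 * lc2 * g * math.cos(t1 + t2 - math.pi / 2.0)
        phi1 = (-m2 * l1 * lc2 * w2 ** 2 * math.sin(t2)
                - 2 * m2 * l1 * lc2 * w2 * w1 * math.sin(t2)
                + (m1 * lc1 + m2 * l1) * g * math.cos(t1 - math.pi / 2.0)
                + phi2)
        ddtheta2 = ((torque + d2 / d1 * phi1
                     - m2 * l1 * lc2 * w1 ** 2 * math.sin(t2) - phi2)
                    / (m2 * lc2 ** 2 + I2 - d2 ** 2 / d1))
        ddtheta1 = -(d2 * ddtheta2 + phi1) / d1
        return np.array([w1, w2, ddtheta1, ddtheta2])

    @staticmethod
    def _wrap(angle: float) -> float:
        return (angle + math.pi) % (2 * math.pi) - math.pi

    def step(self, action: int):
        if self._s is None:
            raise RuntimeError("call reset() before step()")
        if action not in (0, 1, 2):
            raise ValueError(f"invalid action {action}")
        torque = self.torques[action]
        s = self._s
        dt = self.dt
        k1 = self._dsdt(s, torque)
        k2 = self._dsdt(s + dt / 2 * k1, torque)
        k3 = self._dsdt(s + dt / 2 * k2, torque)
        k4 = self._dsdt(s + dt * k3, torque)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        s[0] = self._wrap(s[0])
        s[1] = self._wrap(s[1])
        s[2] = float(np.clip(s[2], -self._w1_max, self._w1_max))
        s[3] = float(np.clip(s[3], -self._w2_max, self._w2_max))
        self._s = s
        self._steps += 1
        terminated = bool(-math.cos(s[0]) - math.cos(s[1] + s[0]) > 1.0)
        truncated = bool(self._steps >= self.step_limit and not terminated)
        return self._obs(), -1.0, terminated, truncated


_REFERENCE_ENVS = {"cartpole": CartPole, "mountain_car": MountainCar,
                   "acrobot": Acrobot}


def make_reference_env(name: str) -> EnvAdapter:
    """Instantiate a bundled benchmark by name: cartpole, mountain_car or
    acrobot."""
    try:
        return _REFERENCE_ENVS[name]()
    except KeyError:
        raise ValueError(
            f"unknown environment {name!r}; "
            f"choose from {sorted(_REFERENCE_ENVS)}") from None


class GymnasiumAdapter:
    """Wrap any Gymnasium-style environment object (duck-typed: the package
    does not import gymnasium itself) into the adapter contract."""

    def __init__(self, gym_env, step_limit: int,
                 observation_ranges: np.ndarray,
                 observation_scales: np.ndarray | None = None):
        self._env = gym_env
        self.observation_dim = int(observation_ranges.shape[0])
        self.n_actions = int(gym_env.action_space.n)
        self.step_limit = int(step_limit)
        self.observation_ranges = np.asarray(observation_ranges, float)
        self.observation_scales = (
            np.abs(self.observation_ranges).max(axis=1)
            if observation_scales is None
            else np.asarray(observation_scales, float))

    def reset(self, seed: int | None = None) -> np.ndarray:
        obs, _info = self._env.reset(seed=seed)
        return np.asarray(obs, dtype=np.float64)

    def step(self, action: int):
        obs, reward, terminated, truncated, _info = self._env.step(action)
        return (np.asarray(obs, dtype=np.float64), float(reward),
                bool(terminated), bool(truncated))
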