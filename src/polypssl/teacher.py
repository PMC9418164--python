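"""Mean-teacher bookkeeping: the teacher's weights are an exponential moving
average (EMA) of the student's, theta'_t = alpha * theta'_{t-1} + (1 - alpha) * theta_t.

alpha = 0 degenerates to the pi-model (teacher == current student); alpha = 1
freezes the teacher at its initial copy.  The default alpha = 0.999 follows
the mean-teacher convention for long (thousands of steps) schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TeacherState", "init_teacher", "ema_update"]


def _param_dict(student) -> dict[str, np.ndarray]:
    if hasattr(student, "named_parameters"):
        return {n: p.data for n, p in student.named_parameters()}
    return dict(student)


@dataclass
class TeacherState:
    shadow_params: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = 0.999
    step: int = 0

    def apply_to(self, net) -> None:
        """Load the shadow parameters into a network of matching structure."""
        net.load_state_dict(self.shadow_params)


def init_teacher(student, alpha: float = 0.999) -> TeacherState:
    """Teacher starts as an exact copy of the student (t = 0 convention)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    shadow = {n: np.array(v, copy=True) for n, v in _param_dict(student).items()}
    return TeacherState(shadow_params=shadow, alpha=alpha, step=0)


def ema_update(state: TeacherState, student) -> TeacherState:
    """One EMA step; mutates and returns ``state``, never the student."""
    params = _param_dict(student)
    if set(params) != set(state.shadow_params):
        raise ValueError("teacher/student parameter sets differ")
    a = state.alpha
    for name, theta in params.items():
        shadow = state.shadow_params[name]
        if shadow.shape != theta.shape:
            raise ValueError(f"shape mismatch for parameter {name!r}: "
                             f"{shadow.shape} vs {theta.shape}")
        shadow *= a
        shadow += (1.0 - a) * theta
    state.step += 1
    return state
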