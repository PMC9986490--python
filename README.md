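# aifintercept

Neural active inference for locomotor interception: a G-learning agent that
learns to intercept a moving target whose speed changes semi-predictably
partway through each approach.

## The problem

In a classic perceptual-motor task, a subject controls their speed of
self-motion along a straight path with a foot pedal (a first-order lag
plant) to intercept a target moving toward an invisible interception point.
The target starts at one of three speeds and, 2.5–3.25 s into the episode,
ramps over 500 ms to a final speed drawn from N(15, 5²) m/s truncated at
±1 sd — so it *usually* accelerates. A purely reactive controller that
matches the target's current (first-order) time-to-contact tends to arrive
late; skilled humans speed up early, anticipating the likely acceleration.

This package asks whether an active inference agent reproduces that
behavior. The agent estimates **negative expected free energy (EFE)** per
action with a two-headed neural network (shared trunk; a G-value head and a
next-observation transition head) and learns by a Q-learning-style bootstrap
("G-learning") with experience replay and a target network. Its per-step
reward is

    R_t = log p̃(o_{t+1})  +  ‖ô_{t+1} − o_{t+1}‖²
          (instrumental)      (epistemic)

where the prior preference p̃ is a Gaussian over the *speed difference*
d = v_agent − v_required in a one-dimensional prior space (v_required =
agent distance ÷ target first-order TTC), and the epistemic term is the
transition head's prediction error. With discount γ = 0 the agent converges
to reactive, first-order interception; with γ = 0.99 it anticipates the
target's likely speed change — and it anticipates more strongly when its
vehicle is made less responsive (pedal lag coefficient halved).

Audience: computational/cognitive scientists studying visually guided
action, and RL researchers interested in scaled-up active inference with
prior preference design.

## Worked example

Train the full agent for 800 episodes (≈2 min on one CPU) and analyze it:

```python
import numpy as np
from aifintercept import (ActiveInferenceAgent, AgentConfig, EnvConfig,
                          run_trial, evaluate, windowed_average,
                          summarize_ttc, anticipation_index, success_rate)

agent = ActiveInferenceAgent(AgentConfig(seed=0))          # gamma = 0.99
log = run_trial(agent, EnvConfig(), n_episodes=800, seed=42)

wa = windowed_average(log.episodes["success"].to_numpy(float), 100)
print(f"final windowed success: {wa[-1]:.2f}")
print(f"greedy evaluation:      "
      f"{success_rate(evaluate(agent, EnvConfig(), 100, seed=7)):.2f}")
summ = summarize_ttc(log, min_episode=400)
print(summ[["agent_median", "target_fo_median", "target_actual_median",
            "anticipation_index"]].round(2))
print(f"anticipation index: {anticipation_index(summ):.2f}")
```

Output:

```
final windowed success: 0.97
greedy evaluation:      0.99
                   agent_median  target_fo_median  target_actual_median  anticipation_index
target_init_speed
8.18                       2.00              2.60                  1.54                0.57
9.47                       1.41              1.94                  1.30                0.82
11.25                      0.92              1.10                  0.88                0.83
anticipation index: 0.74
```

Reading: the trained agent intercepts ~97% of targets. At the moment the
target begins changing speed, the agent's own time-to-contact (2.00 s for
the slowest targets) is already *below* the target's first-order TTC
(2.60 s) and partway toward its true ramp-aware TTC (1.54 s): the agent has
sped up in anticipation of the likely acceleration (index ≈ 0.74 on the
0 = reactive, 1 = fully anticipatory scale). Training the same agent with
`gamma=0.0` yields an index near 0.2 — the reactive, constant-bearing-style
strategy — while halving the lag multiplier (a less responsive vehicle)
raises the index to ~0.85 over a 1,500-episode run.

The same runs are available from the shell:

```bash
aif-intercept train --agent aif_full --gamma 0.99 --episodes 800 \
    --seed 0 --out runs/aif
aif-intercept analyze runs/aif/episodes.jsonl --cutoff 400
aif-intercept prior --x-t 20 --v-t 10 --x-s 25 --v-s 0   # Fig-3-style dump
```

## Package layout

| module | contents |
|---|---|
| `aifintercept.env` | 60 Hz interception simulator, pedal lag, TTC kinematics |
| `aifintercept.priors` | prior mapping function and instrumental reward |
| `aifintercept.network` | two-headed MLP, hand-derived gradients, Adam |
| `aifintercept.replay` | FIFO replay buffer with uniform sampling |
| `aifintercept.agent` | G-learning active inference agent |
| `aifintercept.baselines` | sparse-reward DQN, instrumental-only ablation |
| `aifintercept.experiment` | trials, success curves, TTC anticipation analysis |
| `aifintercept.cli` | `aif-intercept train / grid / analyze / prior / plot` |

See `docs/methods.md` for the model, its assumptions, and every design
decision the task description left open.
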