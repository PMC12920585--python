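"""Evolve a spiking pole-balancer.

Runs NEAT (population 50) on the bundled CartPole task with the sign-split
two-neurons-per-feature encoding and Izhikevich neurons, stopping early
once a candidate's 10-episode mean return reaches the 500-step ceiling,
then re-scores the best network on fresh episodes.  A full 50-generation
run (scripts/acceptance.py) reliably reaches a mean of 500; this shortened
demo usually gets there in a couple of minutes.
"""

from neatsnn import benchmarks

report = benchmarks.run_rl_benchmark(
    "cartpole", "small", "izhikevich", seed=1,
    generations=25, fitness_goal=500.0, eval_episodes=20)

gens = report.evolution.generations_run
print(f"evolved for {gens} generations; "
      f"final training fitness {report.evolution.best_fitness:.1f}")
print(f"held-out evaluation over 20 fresh episodes: "
      f"mean {report.eval_mean:.2f}, best episode "
      f"{report.best_episode_return:.0f}")

# Meaning: a return of 500 is a full episode with the pole balanced; the
# held-out mean shows how robust the evolved controller is to unseen
# initial states (the training fitness alone can be optimistic).
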