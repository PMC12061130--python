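# Example run config: full model vs ablations and baselines on two tasks.
environments:
  - preset: gaussian_base          # means 0.8 vs 0.7, sigma 0.1
  - preset: bernoulli_10arm        # 0.9 vs nine 0.8 arms
  # Inline environments are also accepted:
  # - kind: bernoulli
  #   probabilities: [0.9, 0.8]
  #   name: two_arm                # unverified condition preset equivalent

agents:
  - name: opal_star
    preset: fig2                   # [alpha_c, alpha_actor, beta] = [.01, .38, .25]
    label: opal_star
  - name: opal_k0
    preset: fig2
    label: opal_k0
  - name: opal_g_only
    preset: fig2
    label: opal_g_only
  - name: q_softmax
    params: {alpha: 0.1, beta: 2.0}
  - name: ucb
    params: {c: 1.0}

horizon: 2000
n_sims: 200
base_seed: 0
plot: true
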