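{
 "n_features": 60,
 "names": [
  "Fpz-Cz.absolute_power.delta",
  "Fpz-Cz.absolute_power.sawtooth",
  "Fpz-Cz.absolute_power.theta",
  "Fpz-Cz.absolute_power.alpha",
  "Fpz-Cz.absolute_power.beta",
  "Fpz-Cz.relative_power.delta",
  "Fpz-Cz.relative_power.sawtooth",
  "Fpz-Cz.relative_power.theta",
  "Fpz-Cz.relative_power.alpha",
  "Fpz-Cz.relative_power.beta",
  "Fpz-Cz.center_frequency.delta",
  "Fpz-Cz.center_frequency.sawtooth",
  "Fpz-Cz.center_frequency.theta",
  "Fpz-Cz.center_frequency.alpha",
  "Fpz-Cz.center_frequency.beta",
  "Fpz-Cz.max_power.delta",
  "Fpz-Cz.max_power.sawtooth",
  "Fpz-Cz.max_power.theta",
  "Fpz-Cz.max_power.alpha",
  "Fpz-Cz.max_power.beta",
  "Fpz-Cz.activity",
  "Fpz-Cz.mobility",
  "Fpz-Cz.complexity",
  "Fpz-Cz.skewness",
  "Fpz-Cz.kurtosis",
  "Fpz-Cz.shannon_entropy",
  "Fpz-Cz.spectral_entropy",
  "Fpz-Cz.kolmogorov_entropy",
  "Fpz-Cz.max_lyapunov",
  "Fpz-Cz.c0_complexity",
  "Pz-Oz.absolute_power.delta",
  "Pz-Oz.absolute_power.sawtooth",
  "Pz-Oz.absolute_power.theta",
  "Pz-Oz.absolute_power.alpha",
  "Pz-Oz.absolute_power.beta",
  "Pz-Oz.relative_power.delta",
  "Pz-Oz.relative_power.sawtooth",
  "Pz-Oz.relative_power.theta",
  "Pz-Oz.relative_power.alpha",
  "Pz-Oz.relative_power.beta",
  "Pz-Oz.center_frequency.delta",
  "Pz-Oz.center_frequency.sawtooth",
  "Pz-Oz.center_frequency.theta",
  "Pz-Oz.center_frequency.alpha",
  "Pz-Oz.center_frequency.beta",
  "Pz-Oz.max_power.delta",
  "Pz-Oz.max_power.sawtooth",
  "Pz-Oz.max_power.theta",
  "Pz-Oz.max_power.alpha",
  "Pz-Oz.max_power.beta",
  "Pz-Oz.activity",
  "Pz-Oz.mobility",
  "Pz-Oz.complexity",
  "Pz-Oz.skewness",
  "Pz-Oz.kurtosis",
  "Pz-Oz.shannon_entropy",
  "Pz-Oz.spectral_entropy",
  "Pz-Oz.kolmogorov_entropy",
  "Pz-Oz.max_lyapunov",
  "Pz-Oz.c0_complexity"
 ],
 "naming": "<channel>.<feature>[.<band>]"
}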