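stage 1: coarse
  mu=-1.40 sigma=0.50: 1.016 +- 0.008 %/min
  mu=-1.20 sigma=0.50: 1.130 +- 0.009 %/min
  mu=-1.00 sigma=0.50: 1.263 +- 0.017 %/min
  mu=-0.80 sigma=0.50: 1.406 +- 0.010 %/min
  mu=-1.40 sigma=0.75: 1.027 +- 0.014 %/min
  mu=-1.20 sigma=0.75: 1.112 +- 0.016 %/min
  mu=-1.00 sigma=0.75: 1.248 +- 0.017 %/min
  mu=-0.80 sigma=0.75: 1.374 +- 0.014 %/min
  mu=-1.40 sigma=1.00: 1.026 +- 0.013 %/min
  mu=-1.20 sigma=1.00: 1.113 +- 0.012 %/min
  mu=-1.00 sigma=1.00: 1.209 +- 0.010 %/min
  mu=-0.80 sigma=1.00: 1.317 +- 0.009 %/min
stage 2: refine
  sigma=0.50: mu*=-1.080 -> 1.218 +- 0.008 %/min
  sigma=0.75: mu*=-1.056 -> 1.230 +- 0.009 %/min
  sigma=1.00: mu*=-0.999 -> 1.226 +- 0.009 %/min
selected: meander_mu=-1.080 meander_sigma=0.50 (rate 1.218)
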