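# Canonical severity model: two exogenous latents (communication,
# comorbidities) with free covariance drive the endogenous global-severity
# latent; motor, vision and feeding are direct indicators of global
# severity.  First indicator of each latent fixed to 1 for identification.
observed:
- motor
- insomnia
- sleepiness
- seizures
- alertness
- comm_clinician
- csbs
- vision
- feeding
latents:
- communication
- comorbidities
- global
measurement:
- {indicator: motor, latent: global, fixed: 1.0}
- {indicator: insomnia, latent: comorbidities, fixed: 1.0}
- {indicator: sleepiness, latent: comorbidities}
- {indicator: seizures, latent: comorbidities}
- {indicator: alertness, latent: comorbidities}
- {indicator: comm_clinician, latent: communication, fixed: 1.0}
- {indicator: csbs, latent: communication}
- {indicator: vision, latent: global}
- {indicator: feeding, latent: global}
structural:
- {from: communication, to: global}
- {from: comorbidities, to: global}
psi:
  free:
  - [communication, communication]
  - [comorbidities, comorbidities]
  - [communication, comorbidities]
  - [global, global]
  fixed: []
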