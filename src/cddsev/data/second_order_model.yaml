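# Alternative orientation of the severity construct: a single exogenous
# global-severity latent drives the communication and comorbidities
# sub-latents (second-order reading of the path diagram).
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
- {from: global, to: communication}
- {from: global, to: comorbidities}
psi:
  free:
  - [communication, communication]
  - [comorbidities, comorbidities]
  - [global, global]
  fixed: []
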