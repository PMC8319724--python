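# Phenotype keyword vocabulary.
#
# Substring matching on lowercased, trimmed terms.  Flag categories drive the
# lethal / sterile / lifespan flags (essential is derived as lethal OR
# sterile); stage categories bin a gene by the earliest developmental stage
# any of its terms touches.  Extend or edit freely: the matcher reads this
# file, nothing is hard-coded.
flags:
  lethal:
    - lethal
  sterile:
    - sterile
  lifespan:
    - life span
    - lifespan
stages:
  early:
    - sterile
    - embryonic
  middle:
    - development
    - larval
  late:
    - locomotion
    - neurotransmitter
# Extra descriptive categories tallied when requested (pleiotropy profile).
extra:
  slow_growth:
    - slow growth
  transgene:
    - transgene
  body_posture:
    - body posture
  pharyngeal_pumping:
    - pharyngeal pumping
  brood:
    - brood
  dauer:
    - dauer
  roaming:
    - roaming
  aldicarb:
    - aldicarb
  fat:
    - fat
  oxidative_stress:
    - oxidative stress
  rachis:
    - rachis
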