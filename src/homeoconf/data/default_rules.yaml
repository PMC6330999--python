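# Default five-rule base for homoeolog confidence.
#
# The two extreme rules pin down what an unambiguously good and an
# unambiguously bad candidate pair look like; the middle rules grade the
# rest, weighting the synteny score most heavily.  Edit a copy of this file
# and pass it via --rules / ruleset= to change the behavior.
# The middle rules deliberately condition on synteny alone: mixing
# quality-increasing terms (low distance, low copy number) into rules with
# mid/low consequents makes the crisp output non-monotone in those inputs
# under centroid defuzzification, because weakening such a rule removes
# membership mass from the middle of the confidence scale.
rules:
  - if: "synteny is high and distance is low and copynr is low"
    then: very high
  - if: "synteny is high"
    then: high
  - if: "synteny is med"
    then: med
  - if: "synteny is low"
    then: low
  - if: "synteny is low and distance is high and copynr is high"
    then: very low
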