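# Illustrative lives-saved scenario. Baseline mortality rates follow
# published national figures (stillbirth 18/1000 births, neonatal 21/1000,
# post-neonatal under-five 17/1000 live births, maternal 239/100000); the
# cause split and intervention-effect matrix are illustrative placeholders,
# not a calibrated country database.
start_year: 2016
end_year: 2030
births_per_year: 570000
birth_growth_rate: 0.0
combination: residual
groups:
  - name: maternal
    rate_per: 100000
    cause_rates:
      haemorrhage: 60
      maternal_sepsis: 40
      hypertensive_disorders: 50
      other_maternal: 89
  - name: stillbirth
    rate_per: 1000
    cause_rates:
      intrapartum_stillbirth: 8
      antepartum_stillbirth: 10
  - name: neonatal
    rate_per: 1000
    cause_rates:
      prematurity: 7
      intrapartum_events: 6
      neonatal_sepsis: 5
      other_neonatal: 3
  - name: postneonatal_under5
    rate_per: 1000
    cause_rates:
      pneumonia: 6
      diarrhoea: 4
      other_child: 7
interventions:
  - name: sba
    effectiveness:
      haemorrhage: 0.40
      maternal_sepsis: 0.35
      intrapartum_stillbirth: 0.45
      intrapartum_events: 0.45
    affected_fraction:
      haemorrhage: 0.9
      maternal_sepsis: 0.8
      intrapartum_stillbirth: 0.9
      intrapartum_events: 0.9
    baseline_coverage: {base_year: 2016, base_coverage: 63, arc: 0.0}
    scaleup_coverage: {base_year: 2016, base_coverage: 63, arc: 11.7}
  - name: anc_skilled
    effectiveness:
      antepartum_stillbirth: 0.20
      hypertensive_disorders: 0.30
      prematurity: 0.15
    affected_fraction:
      antepartum_stillbirth: 0.8
      hypertensive_disorders: 0.7
      prematurity: 0.6
    baseline_coverage: {base_year: 2016, base_coverage: 86, arc: 0.0}
    scaleup_coverage: {base_year: 2016, base_coverage: 86, arc: 7.7}
  - name: td2plus
    effectiveness:
      neonatal_sepsis: 0.30
    affected_fraction:
      neonatal_sepsis: 0.4
    baseline_coverage: {base_year: 2016, base_coverage: 65, arc: 0.0}
    scaleup_coverage: {base_year: 2016, base_coverage: 65, arc: 2.4}
  - name: ort
    effectiveness:
      diarrhoea: 0.69
    affected_fraction:
      diarrhoea: 1.0
    baseline_coverage: {base_year: 2016, base_coverage: 61.4, arc: 0.0}
    scaleup_coverage: {base_year: 2016, base_coverage: 61.4, arc: 2.5}
  - name: cpnm
    effectiveness:
      pneumonia: 0.70
    affected_fraction:
      pneumonia: 0.9
    baseline_coverage: {base_year: 2016, base_coverage: 84.9, arc: 0.0}
    scaleup_coverage: {base_year: 2016, base_coverage: 84.9, arc: 8.2}
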