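{
 "options": [
  {
   "option_id": 1,
   "group": "large",
   "r_min": 22.6,
   "r_max": 25.0,
   "m_min": 2.0,
   "m_max": 20.0,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 25.0,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 2,
   "group": "large",
   "r_min": 20.1,
   "r_max": 22.5,
   "m_min": 2.0,
   "m_max": 20.0,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 22.5,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 3,
   "group": "large",
   "r_min": 18.4,
   "r_max": 20.8,
   "m_min": 2.0,
   "m_max": 20.0,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 20.8,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 4,
   "group": "large",
   "r_min": 16.3,
   "r_max": 18.7,
   "m_min": 2.0,
   "m_max": 18.7,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 18.7,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 5,
   "group": "large",
   "r_min": 14.3,
   "r_max": 16.7,
   "m_min": 2.0,
   "m_max": 16.7,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 16.7,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 6,
   "group": "large",
   "r_min": 12.4,
   "r_max": 14.8,
   "m_min": 2.0,
   "m_max": 14.8,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 14.8,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 7,
   "group": "large",
   "r_min": 10.7,
   "r_max": 13.1,
   "m_min": 2.0,
   "m_max": 13.1,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 13.1,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 8,
   "group": "large",
   "r_min": 9.0,
   "r_max": 11.4,
   "m_min": 2.0,
   "m_max": 11.4,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 11.4,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 9,
   "group": "large",
   "r_min": 7.5,
   "r_max": 9.9,
   "m_min": 2.0,
   "m_max": 9.9,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 9.9,
   "rof_modulation": 8.0,
   "esad": null
  },
  {
   "option_id": 10,
   "group": "large",
   "r_min": 6.1,
   "r_max": 8.5,
   "m_min": 2.0,
   "m_max": 8.5,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 8.5,
   "rof_modulation": 6.0,
   "esad": null
  },
  {
   "option_id": 11,
   "group": "large",
   "r_min": 5.0,
   "r_max": 7.2,
   "m_min": 2.0,
   "m_max": 7.2,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 7.2,
   "rof_modulation": 6.0,
   "esad": null
  },
  {
   "option_id": 12,
   "group": "large",
   "r_min": 5.0,
   "r_max": 6.0,
   "m_min": 2.0,
   "m_max": 6.0,
   "applicator_cm": 25.0,
   "reference_field": "20x20",
   "rof_range": 6.0,
   "rof_modulation": 4.0,
   "esad": null
  },
  {
   "option_id": 13,
   "group": "deep",
   "r_min": 29.6,
   "r_max": 32.0,
   "m_min": 2.0,
   "m_max": 10.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 32.0,
   "rof_modulation": 10.0,
   "esad": 180.8
  },
  {
   "option_id": 14,
   "group": "deep",
   "r_min": 27.1,
   "r_max": 29.5,
   "m_min": 2.0,
   "m_max": 10.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 29.5,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 15,
   "group": "deep",
   "r_min": 24.6,
   "r_max": 27.0,
   "m_min": 2.0,
   "m_max": 10.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 27.0,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 16,
   "group": "deep",
   "r_min": 22.1,
   "r_max": 24.5,
   "m_min": 2.0,
   "m_max": 10.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 24.5,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 17,
   "group": "deep",
   "r_min": 20.1,
   "r_max": 22.0,
   "m_min": 2.0,
   "m_max": 10.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 22.0,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 18,
   "group": "small",
   "r_min": 17.6,
   "r_max": 20.0,
   "m_min": 2.0,
   "m_max": 20.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 20.0,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 19,
   "group": "small",
   "r_min": 15.3,
   "r_max": 17.7,
   "m_min": 2.0,
   "m_max": 17.7,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 17.7,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 20,
   "group": "small",
   "r_min": 12.6,
   "r_max": 15.0,
   "m_min": 2.0,
   "m_max": 15.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 15.0,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 21,
   "group": "small",
   "r_min": 10.8,
   "r_max": 13.2,
   "m_min": 2.0,
   "m_max": 13.2,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 13.2,
   "rof_modulation": 10.0,
   "esad": null
  },
  {
   "option_id": 22,
   "group": "small",
   "r_min": 8.7,
   "r_max": 11.1,
   "m_min": 2.0,
   "m_max": 11.1,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 11.1,
   "rof_modulation": 10.0,
   "esad": 171.9
  },
  {
   "option_id": 23,
   "group": "small",
   "r_min": 6.6,
   "r_max": 9.0,
   "m_min": 2.0,
   "m_max": 9.0,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 9.0,
   "rof_modulation": 8.0,
   "esad": null
  },
  {
   "option_id": 24,
   "group": "small",
   "r_min": 5.0,
   "r_max": 6.9,
   "m_min": 2.0,
   "m_max": 6.9,
   "applicator_cm": 14.0,
   "reference_field": "10x10",
   "rof_range": 6.9,
   "rof_modulation": 6.0,
   "esad": null
  }
 ]
}
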