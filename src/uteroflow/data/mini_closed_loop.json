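{
 "closed_loop": true,
 "segments": [
  {
   "id": 1,
   "name": "aorta",
   "region": "systemic_artery",
   "side": "central",
   "length_cm": 20.0,
   "area_np_cm2": 4.5,
   "area_p_cm2": 4.5,
   "multiplicity": 1,
   "parent_ids": [
    "AV"
   ],
   "bed_id": null,
   "c0_cm_s": null,
   "is_vena_cava": false
  },
  {
   "id": 2,
   "name": "left brachial artery",
   "region": "systemic_artery",
   "side": "central",
   "length_cm": 20.0,
   "area_np_cm2": 1.1380915379639502,
   "area_p_cm2": 1.1380915379639502,
   "multiplicity": 1,
   "parent_ids": [
    1
   ],
   "bed_id": 11,
   "c0_cm_s": null,
   "is_vena_cava": false
  },
  {
   "id": 3,
   "name": "descending artery",
   "region": "systemic_artery",
   "side": "central",
   "length_cm": 20.0,
   "area_np_cm2": 4.000062782255114,
   "area_p_cm2": 4.000062782255114,
   "multiplicity": 1,
   "parent_ids": [
    1
   ],
   "bed_id": 12,
   "c0_cm_s": null,
   "is_vena_cava": false
  },
  {
   "id": 4,
   "name": "arm vein",
   "region": "systemic_vein",
   "side": "central",
   "length_cm": 20.0,
   "area_np_cm2": 1.7782680280686722,
   "area_p_cm2": 1.7782680280686722,
   "multiplicity": 1,
   "parent_ids": [
    "bed:11"
   ],
   "bed_id": null,
   "c0_cm_s": null,
   "is_vena_cava": false
  },
  {
   "id": 5,
   "name": "body vein",
   "region": "systemic_vein",
   "side": "central",
   "length_cm": 20.0,
   "area_np_cm2": 6.250098097273615,
   "area_p_cm2": 6.250098097273615,
   "multiplicity": 1,
   "parent_ids": [
    "bed:12"
   ],
   "bed_id": null,
   "c0_cm_s": null,
   "is_vena_cava": false
  },
  {
   "id": 6,
   "name": "vena cava",
   "region": "systemic_vein",
   "side": "central",
   "length_cm": 10.0,
   "area_np_cm2": 7.031249999999998,
   "area_p_cm2": 7.031249999999998,
   "multiplicity": 1,
   "parent_ids": [
    4,
    5
   ],
   "bed_id": "RA",
   "c0_cm_s": null,
   "is_vena_cava": true
  },
  {
   "id": 7,
   "name": "pulmonary artery",
   "region": "pulmonary_artery",
   "side": "central",
   "length_cm": 5.0,
   "area_np_cm2": 4.0,
   "area_p_cm2": 4.0,
   "multiplicity": 1,
   "parent_ids": [
    "PV"
   ],
   "bed_id": 13,
   "c0_cm_s": null,
   "is_vena_cava": false
  },
  {
   "id": 8,
   "name": "pulmonary vein",
   "region": "pulmonary_vein",
   "side": "central",
   "length_cm": 5.0,
   "area_np_cm2": 4.5,
   "area_p_cm2": 4.5,
   "multiplicity": 1,
   "parent_ids": [
    "bed:13"
   ],
   "bed_id": "LA",
   "c0_cm_s": null,
   "is_vena_cava": false
  }
 ],
 "beds": [
  {
   "id": 11,
   "name": "arm",
   "arterial_terminal_ids": [
    2
   ],
   "venous_terminal_ids": [
    4
   ],
   "r0_total": NaN,
   "compliance_total": NaN,
   "p_tm0": NaN,
   "p_zf": 6666.1,
   "kind": "pressure_dependent",
   "alpha": 0.15
  },
  {
   "id": 12,
   "name": "body",
   "arterial_terminal_ids": [
    3
   ],
   "venous_terminal_ids": [
    5
   ],
   "r0_total": NaN,
   "compliance_total": NaN,
   "p_tm0": NaN,
   "p_zf": 6666.1,
   "kind": "pressure_dependent",
   "alpha": 0.85
  },
  {
   "id": 13,
   "name": "lung",
   "arterial_terminal_ids": [
    7
   ],
   "venous_terminal_ids": [
    8
   ],
   "r0_total": NaN,
   "compliance_total": NaN,
   "p_tm0": NaN,
   "p_zf": 6666.1,
   "kind": "pressure_dependent",
   "alpha": NaN
  }
 ],
 "heart": {
  "AV": 1,
  "PV": 7,
  "RA": [
   6
  ],
  "LA": [
   8
  ]
 }
}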