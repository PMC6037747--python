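{
  "note": "calibrated trafficking rates; regenerate with spinetraffic.calibration.calibrate",
  "parameters": {
    "k_f2": 0.09450000000000001,
    "k_b2": 4999.9,
    "k_f3": 200.00000000000003,
    "k_b3": 7.100169883294186,
    "D_free": 0.4
  },
  "report": {
    "feasible": true,
    "targets": [
      {
        "name": "rest_cyt_per_spine",
        "target": 100.0,
        "tolerance": 10.0,
        "achieved": 91.37777658764581,
        "within_tolerance": true
      },
      {
        "name": "rest_synaptic_per_psd",
        "target": 110.0,
        "tolerance": 10.0,
        "achieved": 118.31352310611251,
        "within_tolerance": true
      },
      {
        "name": "ltp1_psd1",
        "target": 119.0,
        "tolerance": 6.8,
        "achieved": 118.93655563384117,
        "within_tolerance": true
      },
      {
        "name": "ltp12_psd3_mag",
        "target": 15.8,
        "tolerance": 3.7,
        "achieved": 15.253863202268127,
        "within_tolerance": true
      },
      {
        "name": "ltp1234_psd5_mag",
        "target": 29.4,
        "tolerance": 5.35,
        "achieved": 34.396506222186716,
        "within_tolerance": true
      },
      {
        "name": "ltd1234_psd5",
        "target": 24.8,
        "tolerance": 7.8,
        "achieved": 21.459837299786045,
        "within_tolerance": true
      }
    ],
    "benchmarks": [
      {
        "name": "rest_synaptic_count",
        "reported_mean": 100.0,
        "reported_std": null,
        "band": [
          100.0,
          120.0
        ],
        "meanfield_prediction": 118.31224739255592,
        "stochastic_mean": 114.61704918032787,
        "stochastic_sem": null,
        "within_1std": true
      },
      {
        "name": "ltp1_psd1",
        "reported_mean": 119.0,
        "reported_std": 6.8,
        "band": null,
        "meanfield_prediction": 118.93655563384117,
        "stochastic_mean": 115.21054827240543,
        "stochastic_sem": 2.623443580946555,
        "within_1std": true
      },
      {
        "name": "ltp1_psd2_mag",
        "reported_mean": 16.3,
        "reported_std": 7.5,
        "band": null,
        "meanfield_prediction": 6.844595409599963,
        "stochastic_mean": 7.775060492515787,
        "stochastic_sem": 1.6401106511461943,
        "within_1std": false
      },
      {
        "name": "ltp12_psd3_mag",
        "reported_mean": 15.8,
        "reported_std": 3.7,
        "band": null,
        "meanfield_prediction": 15.253863202268127,
        "stochastic_mean": 11.333458444840126,
        "stochastic_sem": 1.2903627800665212,
        "within_1std": false
      },
      {
        "name": "ltp12_psd5_mag",
        "reported_mean": 18.4,
        "reported_std": 4.8,
        "band": null,
        "meanfield_prediction": 15.22748615501504,
        "stochastic_mean": 15.851404746543508,
        "stochastic_sem": 1.3826936732756778,
        "within_1std": true
      },
      {
        "name": "ltp123_psd1",
        "reported_mean": 96.3,
        "reported_std": 6.0,
        "band": null,
        "meanfield_prediction": 106.71949569182593,
        "stochastic_mean": 100.74267991720588,
        "stochastic_sem": 3.0316978296343264,
        "within_1std": false
      },
      {
        "name": "ltp123_psd4_mag",
        "reported_mean": 24.6,
        "reported_std": 6.55,
        "band": null,
        "meanfield_prediction": 24.51852777958382,
        "stochastic_mean": 24.83182527841215,
        "stochastic_sem": 1.7832398116131292,
        "within_1std": true
      },
      {
        "name": "ltp123_psd5_mag",
        "reported_mean": 26.2,
        "reported_std": 6.3,
        "band": null,
        "meanfield_prediction": 24.499138961210758,
        "stochastic_mean": 24.10465450820081,
        "stochastic_sem": 1.4827946652472324,
        "within_1std": true
      },
      {
        "name": "ltp1234_psd5_mag",
        "reported_mean": 29.4,
        "reported_std": 5.35,
        "band": null,
        "meanfield_prediction": 34.396506222186716,
        "stochastic_mean": 35.351591748910444,
        "stochastic_sem": 1.1858281622846345,
        "within_1std": false
      },
      {
        "name": "ltd12_psd3",
        "reported_mean": 13.3,
        "reported_std": 5.5,
        "band": null,
        "meanfield_prediction": 10.803670723583714,
        "stochastic_mean": 14.72844139157669,
        "stochastic_sem": 2.1691279220496864,
        "within_1std": true
      },
      {
        "name": "ltd12_psd4",
        "reported_mean": 17.7,
        "reported_std": 4.54,
        "band": null,
        "meanfield_prediction": 10.79985204792757,
        "stochastic_mean": 11.057989652284297,
        "stochastic_sem": 1.9337537825902409,
        "within_1std": false
      },
      {
        "name": "ltd123_psd5",
        "reported_mean": 13.4,
        "reported_std": 5.2,
        "band": null,
        "meanfield_prediction": 16.06478532484953,
        "stochastic_mean": 14.102601022705754,
        "stochastic_sem": 1.7837774528372967,
        "within_1std": true
      },
      {
        "name": "ltd1234_psd5",
        "reported_mean": 24.8,
        "reported_std": 7.8,
        "band": null,
        "meanfield_prediction": 21.459837299786045,
        "stochastic_mean": 19.041539156861337,
        "stochastic_sem": 1.8169767506405248,
        "within_1std": true
      },
      {
        "name": "seq_ltp12_ltp3_dt2",
        "reported_mean": 137.0,
        "reported_std": 4.4,
        "band": null,
        "meanfield_prediction": 144.00965939088712,
        "stochastic_mean": 143.33253387324564,
        "stochastic_sem": 3.169042405336406,
        "within_1std": false
      },
      {
        "name": "ctrl_post_ltp3_dt2",
        "reported_mean": 117.0,
        "reported_std": 6.0,
        "band": null,
        "meanfield_prediction": 117.32970071590717,
        "stochastic_mean": 118.27462212226425,
        "stochastic_sem": 2.701764931106153,
        "within_1std": true
      },
      {
        "name": "ts_ltp12_psd3_mag_dt1",
        "reported_mean": 6.76,
        "reported_std": 3.1,
        "band": null,
        "meanfield_prediction": 7.149644314119641,
        "stochastic_mean": 5.832898322924362,
        "stochastic_sem": 0.8613374569897756,
        "within_1std": true
      }
    ]
  }
}
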