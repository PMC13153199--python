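"""Calibrated latent weights for the packaged commonality scenarios.

Produced by :func:`foulcast.synthdata.calibrate_fouling_weights` applied
to the packaged scenario targets (fixed search seed 12345); regenerate by
rerunning that function if the targets or the column-noise variance change.
"""

CALIBRATED_WEIGHTS = {
    "Ctrl": {
        "W": [
            [-0.3242601037439343, 0.0, 0.0, -0.5848189993662681, 0.520178336040667, 0.0, 0.3819291581861397],
            [0.7901963431652301, 0.0, 0.0, 0.6869793598911319, 2.048055415896238, 0.0, -1.0700884999049485],
            [0.0, 0.3603804423627477, 0.0, 0.9117273533295593, 0.0, -0.7496634780142345, 0.8064493733978514],
            [0.0, 0.46719559970670266, 0.0, -0.9552742386727207, 0.0, -0.24791149736307, 0.8114116149731251],
            [0.0, 0.0, 1.0569411683208751, 0.0, -0.41243189945127295, -0.32454846793003433, -0.8441493606794928],
            [0.0, 0.0, -0.8661973820369174, 0.0, -0.9512627046668085, 0.9818502702633671, 0.08617756174764318],
        ],
        "v": [-0.33379568483939615, 0.3869743401629426, -0.9882502892247805, -1.233649782239456, -0.3797795120141387, -0.10611965941338893, 2.0174553249330973],
    },
    "Al": {
        "W": [
            [-0.006639411259916924, 0.0, 0.0, -0.05850747505426435, 1.1968529906591834, 0.0, 0.5486938463575222],
            [0.8512339144805026, 0.0, 0.0, -0.1679388281280052, 1.946924217126981, 0.0, -1.11327205188522],
            [0.0, 0.24781706135836085, 0.0, 0.6900616736593795, 0.0, -0.27427760412052893, 1.3480352349248688],
            [0.0, 0.2727455099288499, 0.0, -0.907854537670566, 0.0, -1.4532225594732953, 0.11892360820642561],
            [0.0, 0.0, 0.38044613512740466, 0.0, -0.22728146005954955, 0.37000783016450145, -1.3518769299718523],
            [0.0, 0.0, -0.1812287007557747, 0.0, -0.8514137643374745, -0.9671139307314146, 0.11469742798241485],
        ],
        "v": [-0.29858071892049387, 0.08091467266428373, -0.4656375922628317, 0.6145938482660399, -0.934656631294414, 0.5514419261661526, 2.060659088700733],
    },
    "Fe": {
        "W": [
            [0.05960552243671274, 0.0, 0.0, 0.8182024880277533, 0.26440790016985155, 0.0, 0.8131156684625314],
            [-0.6058319051512309, 0.0, 0.0, -1.358163787655054, 2.203494436920096, 0.0, 2.0319343086937844],
            [0.0, 0.3338064261086258, 0.0, 0.9809923759171254, 0.0, -1.6673439105379328, -1.9862982412939931],
            [0.0, 1.398529418934673, 0.0, 0.31033729984322106, 0.0, 1.4651868853783327, 0.29231112104344475],
            [0.0, 0.0, -0.04434497447512813, 0.0, -0.5596120937142287, -1.9507439916165041, -2.0527240523948476],
            [0.0, 0.0, -0.3640926353784585, 0.0, 0.7926163147094252, 0.44626092267427464, -1.6848255158603358],
        ],
        "v": [0.7154828880976317, -0.3690832044176073, 0.7836197146674184, 1.1402534013658998, -0.03594352787081817, -2.441718970934013, -4.132507481145443],
    },
}
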